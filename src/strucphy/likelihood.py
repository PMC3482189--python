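"""Felsenstein-pruning log-likelihood and ML parameter optimization.

Character data enter as an integer matrix (taxa × sites) with states
0..k−1 and −1 for missing; missing tips contribute a partial-likelihood
vector of ones.  Site patterns are compressed before pruning (identical
columns share one computation), which cannot change the value.  Partial
likelihoods are rescaled per node to avoid underflow on large trees.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .models import SubstitutionModel
from .structure import StructureAlignment
from .trees import Phylogeny

#: optimization bounds for a single branch length (expected subst./site)
MIN_BRANCH, MAX_BRANCH = 1e-8, 20.0


def as_coded(data) -> tuple[list[str], np.ndarray]:
    """Accept a StructureAlignment or a (taxa, codes) pair."""
    if isinstance(data, StructureAlignment):
        return data.taxa, np.asarray(data.codes, dtype=np.int16)
    taxa, codes = data
    return list(taxa), np.asarray(codes, dtype=np.int16)


def encode_nucleotides(rows: list[str]) -> np.ndarray:
    """Nucleotide rows → 4-state coded matrix (A,C,G,U = 0..3; else missing)."""
    lookup = np.full(128, -1, dtype=np.int16)
    for i, b in enumerate("ACGU"):
        lookup[ord(b)] = i
        lookup[ord(b.lower())] = i
    lookup[ord("T")] = lookup[ord("t")] = 3
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    return lookup[np.minimum(arr, 127)]


class _Pruner:
    """Caches tree indexing and site patterns for repeated lnL evaluations."""

    def __init__(self, tree: Phylogeny, taxa: list[str], codes: np.ndarray, k: int):
        codes = np.asarray(codes)
        if codes.size == 0 or codes.shape[1] == 0:
            raise ValueError("zero-length alignment")
        tree_labels = set(tree.tip_labels())
        data_labels = set(taxa)
        if tree_labels != data_labels:
            raise ValueError(
                "tip labels differ between tree and data: "
                f"only in tree {sorted(tree_labels - data_labels)}, "
                f"only in data {sorted(data_labels - tree_labels)}"
            )
        if codes.max(initial=-1) >= k:
            raise ValueError(f"state index exceeds alphabet size {k}")
        self.tree = tree
        self.k = k
        self.nodes = tree.postorder()
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        row_of = {name: i for i, name in enumerate(taxa)}
        # unique site patterns with weights
        patterns, inverse, counts = np.unique(
            codes.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns.T  # (n_taxa_data, n_pat)
        self.weights = counts.astype(float)
        self.n_pat = patterns.shape[0]
        # tip partials: one-hot, missing -> all ones
        self.tip_partials: dict[int, np.ndarray] = {}
        for n in self.nodes:
            if n.is_tip:
                col = self.patterns[row_of[n.label]]
                part = np.zeros((self.n_pat, k))
                obs = col >= 0
                part[obs, col[obs]] = 1.0
                part[~obs, :] = 1.0
                self.tip_partials[self.index[id(n)]] = part
        # per-pattern invariant-class compatibility (for p_inv)
        comp = np.ones((self.n_pat, k), bool)
        for n in self.nodes:
            if n.is_tip:
                comp &= self.tip_partials[self.index[id(n)]] > 0
        self._inv_compat = comp

    def log_likelihood(self, model: SubstitutionModel) -> float:
        if model.k != self.k:
            raise ValueError("model state count does not match data alphabet")
        rates = model.rate_multipliers
        n_cat = len(rates)
        lengths = np.array([n.length for n in self.nodes])
        P = model.transition_matrices(lengths, rates)  # (n_node, n_cat, k, k)
        partials: dict[int, np.ndarray] = {}
        log_scale = np.zeros(self.n_pat)
        for n in self.nodes:
            i = self.index[id(n)]
            if n.is_tip:
                partials[i] = np.broadcast_to(
                    self.tip_partials[i][None, :, :], (n_cat, self.n_pat, self.k)
                )
                continue
            acc = np.ones((n_cat, self.n_pat, self.k))
            for c in n.children:
                ci = self.index[id(c)]
                msg = partials[ci] @ P[ci].transpose(0, 2, 1)
                acc = acc * msg
                del partials[ci]
            scal = acc.max(axis=(0, 2))
            scal[scal <= 0] = 1.0
            acc /= scal[None, :, None]
            log_scale += np.log(scal)
            partials[i] = acc
        root = partials[self.index[id(self.nodes[-1])]]
        site_l = (root @ model.frequencies).mean(axis=0)  # average over Γ cats
        with np.errstate(divide="ignore"):
            log_var = np.log(site_l) + log_scale
        if model.p_inv > 0:
            inv_l = self._inv_compat @ model.frequencies
            with np.errstate(divide="ignore"):
                log_inv = np.log(model.p_inv * inv_l)
            log_site = np.logaddexp(np.log1p(-model.p_inv) + log_var, log_inv)
        else:
            log_site = log_var
        return float(self.weights @ log_site)


    # -- fast per-edge branch optimization -------------------------------
    def _up_pass(self, model: SubstitutionModel):
        """Scaled up partials and per-node transition matrices.

        Returns (P, up, logS) where ``up[i]`` is the scaled conditional
        likelihood below node i, ``logS[i]`` its accumulated per-pattern
        log scaling (summed over the subtree), and P[i] the edge matrix.
        """
        rates = model.rate_multipliers
        n_cat = len(rates)
        lengths = np.array([n.length for n in self.nodes])
        P = model.transition_matrices(lengths, rates)
        up: dict[int, np.ndarray] = {}
        logS: dict[int, np.ndarray] = {}
        for n in self.nodes:
            i = self.index[id(n)]
            if n.is_tip:
                up[i] = np.broadcast_to(
                    self.tip_partials[i][None], (n_cat, self.n_pat, self.k)
                )
                logS[i] = np.zeros(self.n_pat)
                continue
            acc = np.ones((n_cat, self.n_pat, self.k))
            ls = np.zeros(self.n_pat)
            for c in n.children:
                ci = self.index[id(c)]
                acc = acc * (up[ci] @ P[ci].transpose(0, 2, 1))
                ls += logS[ci]
            scal = acc.max(axis=(0, 2))
            scal[scal <= 0] = 1.0
            acc = acc / scal[None, :, None]
            up[i] = acc
            logS[i] = ls + np.log(scal)
        return P, up, logS

    def optimize_branches(self, model: SubstitutionModel,
                          max_cycles: int = 3, tol: float = 1e-4,
                          xatol: float = 1e-6) -> float:
        """Cycle Brent searches over every branch, recomputing outside
        partials freshly per branch; returns the final log-likelihood."""
        from scipy.optimize import minimize_scalar

        rates = model.rate_multipliers
        lnl = self.log_likelihood(model)
        for _ in range(max_cycles):
            prev = lnl
            for v in self.nodes:
                if v.parent is None:
                    continue
                P, up, logS = self._up_pass(model)
                G, logT = self._edge_context_for(v, model, P, up, logS)
                i = self.index[id(v)]
                U, const = up[i], logS[i] + logT
                w_, right, left = model._eigensystem()

                def site_lnl(t: float) -> float:
                    E = np.exp(w_[None, :] * (t * rates)[:, None])
                    Pt = (right[None] * E[:, None, :]) @ left
                    lv = np.einsum("cpi,cij,cpj->cp", G, np.clip(Pt, 0, None), U)
                    site = lv.mean(axis=0)
                    with np.errstate(divide="ignore"):
                        log_var = np.log(site) + const
                    if model.p_inv > 0:
                        inv_l = self._inv_compat @ model.frequencies
                        with np.errstate(divide="ignore"):
                            return float(self.weights @ np.logaddexp(
                                np.log1p(-model.p_inv) + log_var,
                                np.log(model.p_inv * inv_l)))
                    return float(self.weights @ log_var)

                f_old = site_lnl(v.length)
                res = minimize_scalar(lambda t: -site_lnl(t),
                                      bounds=(MIN_BRANCH, MAX_BRANCH),
                                      method="bounded",
                                      options={"xatol": xatol})
                if -res.fun >= f_old:
                    v.length = float(res.x)
            lnl = self.log_likelihood(model)
            if lnl - prev < tol:
                break
        return lnl

    def _edge_context_for(self, v, model: SubstitutionModel, P, up, logS):
        """Outside partial G_v (π-inclusive, indexed by the state at v's
        parent) and its accumulated per-pattern log scaling."""
        pi = model.frequencies
        n_cat = P.shape[1]
        # walk from root down to v's parent, accumulating the outside term
        path = []
        node = v.parent
        while node is not None:
            path.append(node)
            node = node.parent
        path.reverse()  # root ... parent(v)
        g = np.broadcast_to(pi[None, None, :],
                            (n_cat, self.n_pat, self.k)).copy()
        logT = np.zeros(self.n_pat)
        for depth, n in enumerate(path):
            i = self.index[id(n)]
            into = path[depth + 1] if depth + 1 < len(path) else v
            for b in n.children:
                if b is into:
                    continue
                bi = self.index[id(b)]
                g = g * (up[bi] @ P[bi].transpose(0, 2, 1))
                logT = logT + logS[bi]
            if into is not v:
                # transport through the edge above `into`
                ii = self.index[id(into)]
                g = np.einsum("cpi,cij->cpj", g, P[ii])
            scal = g.max(axis=(0, 2))
            scal[scal <= 0] = 1.0
            g = g / scal[None, :, None]
            logT = logT + np.log(scal)
        return g, logT

def log_likelihood(tree: Phylogeny, data, model: SubstitutionModel) -> float:
    """Pruning log-likelihood of ``data`` on ``tree`` under ``model``."""
    taxa, codes = as_coded(data)
    return _Pruner(tree, taxa, codes, model.k).log_likelihood(model)


def optimize(
    tree: Phylogeny,
    data,
    model: SubstitutionModel,
    free: tuple[str, ...] = ("branch_lengths",),
    max_cycles: int = 100,
    tol: float = 1e-6,
    branch_xatol: float = 1e-7,
) -> tuple[Phylogeny, SubstitutionModel, float]:
    """Coordinate-wise ML optimization of branch lengths and rate parameters.

    Cycles Brent searches over each free coordinate until the lnL gain in
    a full cycle drops below ``tol`` (or ``max_cycles``).  The returned
    lnL is never below the starting value.
    """
    if not free:
        raise ValueError("no free parameters to optimize")
    tree = tree.copy()
    taxa, codes = as_coded(data)
    pruner = _Pruner(tree, taxa, codes, model.k)
    lnl = pruner.log_likelihood(model)
    if not np.isfinite(lnl):
        raise ValueError("non-finite log-likelihood at starting point")

    for _ in range(max_cycles):
        prev = lnl
        if "branch_lengths" in free:
            pruner.optimize_branches(model, max_cycles=1, xatol=branch_xatol)
        if "alpha" in free:
            def f_alpha(loga):
                nonlocal model
                m = model.with_(gamma_alpha=float(np.exp(loga)))
                return -pruner.log_likelihood(m)
            res = minimize_scalar(f_alpha, bounds=(np.log(0.02), np.log(100.0)),
                                  method="bounded", options={"xatol": 1e-5})
            model = model.with_(gamma_alpha=float(np.exp(res.x)))
        if "p_inv" in free:
            def f_pinv(p):
                return -pruner.log_likelihood(model.with_(p_inv=float(p)))
            res = minimize_scalar(f_pinv, bounds=(0.0, 0.99),
                                  method="bounded", options={"xatol": 1e-6})
            model = model.with_(p_inv=float(res.x))
        if "frequencies" in free:
            k = model.k

            def f_freq(z):
                pi = np.exp(z - z.max())
                pi /= pi.sum()
                return -pruner.log_likelihood(model.with_(frequencies=pi))

            z0 = np.log(model.frequencies)
            res = minimize(f_freq, z0, method="L-BFGS-B",
                           options={"maxiter": 50})
            pi = np.exp(res.x - res.x.max())
            model = model.with_(frequencies=pi / pi.sum())
        lnl = pruner.log_likelihood(model)
        if lnl - prev < tol:
            break
    return tree, model, lnl
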