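"""End-to-end orchestration: recode → infer + bootstrap → annotate →
collapse → ancestral state reconstruction → reports.

Every run writes its artifacts plus a JSON manifest (parameters, seeds,
SHA-256 of each output) into the output directory, so a run can be
reproduced and checked byte-for-byte from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .asr import MorphCharacter, collapse_weak_nodes, fitch_asr_mp, mk_asr_ml
from .io import read_alignment, read_character_tsv, write_alignment
from .likelihood import encode_nucleotides, optimize
from .models import build_model
from .search import SearchConfig, bootstrap, majority_consensus, search
from .structure import (
    parse_structure,
    project_to_alignment,
    recode_alignment,
    to_protein_letters,
)

log = logging.getLogger("strucphy")


@dataclass
class RunConfig:
    alignment: str
    structure: str
    reference_taxon: str
    characters: list[str] = field(default_factory=list)
    structure_arm: bool = True
    nucleotide_arm: bool = True
    gamma_alpha: float | None = 0.5
    ml_bootstrap: int = 100
    mp_bootstrap: int = 1000
    n_starts: int = 10
    support_threshold: float = 50.0
    drop_uncovered: bool = False
    seed: int = 1
    out_dir: str = "strucphy_run"

    def __post_init__(self):
        if not (0 < self.support_threshold <= 100):
            raise ValueError("support threshold must lie in (0, 100]")
        for path in [self.alignment, self.structure, *self.characters]:
            if not Path(path).exists():
                raise FileNotFoundError(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _run_arm(name: str, taxa, codes, model, cfg: RunConfig, out: Path,
             outputs: dict) -> object:
    """Infer, bootstrap and annotate one analysis arm; returns the
    support-annotated best ML tree."""
    data = (taxa, codes)
    t0 = time.time()
    ml_cfg = SearchConfig(criterion="ml", n_starts=min(cfg.n_starts, 3),
                          seed=cfg.seed)
    best_trees, lnl = search(data, model, ml_cfg)
    best = best_trees[0]
    log.info("[%s] ML search done lnL=%.3f (%.1fs)", name, lnl, time.time() - t0)
    (out / f"{name}_best_ml.nwk").write_text(best.to_newick() + "\n")

    ml_boots = bootstrap(data, SearchConfig(
        criterion="ml", n_starts=1, seed=cfg.seed + 1,
        bootstrap_replicates=cfg.ml_bootstrap), model)
    mp_boots = bootstrap(data, SearchConfig(
        criterion="mp", n_starts=1, seed=cfg.seed + 2,
        bootstrap_replicates=cfg.mp_bootstrap))
    (out / f"{name}_ml_bootstrap.nwk").write_text(
        "\n".join(t.to_newick() for t in ml_boots) + "\n")
    (out / f"{name}_mp_bootstrap.nwk").write_text(
        "\n".join(t.to_newick() for t in mp_boots) + "\n")

    annotated = majority_consensus(ml_boots, annotate_onto=best)
    (out / f"{name}_ml_support.nwk").write_text(
        annotated.to_newick(support=True) + "\n")
    mp_annot = majority_consensus(mp_boots, annotate_onto=best)
    (out / f"{name}_mp_support.nwk").write_text(
        mp_annot.to_newick(support=True) + "\n")
    for key in ("best_ml", "ml_bootstrap", "mp_bootstrap",
                "ml_support", "mp_support"):
        p = out / f"{name}_{key}.nwk"
        outputs[p.name] = _sha256(p)
    return annotated


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every enabled stage; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stage = "setup"
    try:
        taxa, rows = read_alignment(cfg.alignment)
        if cfg.reference_taxon not in taxa:
            raise ValueError(f"reference taxon {cfg.reference_taxon!r} not in alignment")
        pt = parse_structure(Path(cfg.structure).read_text())
        ann = project_to_alignment(pt, rows[taxa.index(cfg.reference_taxon)])

        annotated = None
        if cfg.structure_arm:
            stage = "recode"
            sa = recode_alignment(taxa, rows, ann, drop_uncovered=cfg.drop_uncovered)
            write_alignment(out / "structure_matrix.fasta", sa.taxa,
                            to_protein_letters(sa, missing_char="-"))
            (out / "site_map.tsv").write_text(sa.site_map_table())
            outputs["structure_matrix.fasta"] = _sha256(out / "structure_matrix.fasta")
            outputs["site_map.tsv"] = _sha256(out / "site_map.tsv")
            stage = "structure_arm"
            model = build_model("poisson", 20, "empirical", data=sa.codes,
                                gamma_alpha=cfg.gamma_alpha)
            annotated = _run_arm("structure", sa.taxa, sa.codes, model, cfg,
                                 out, outputs)
        if cfg.nucleotide_arm:
            stage = "nucleotide_arm"
            codes = encode_nucleotides(rows)
            model = build_model("gtr", 4, "empirical", data=codes,
                                gamma_alpha=cfg.gamma_alpha)
            nuc_annotated = _run_arm("nucleotide", taxa, codes, model, cfg,
                                     out, outputs)
            if annotated is None:
                annotated = nuc_annotated

        stage = "asr"
        collapsed = collapse_weak_nodes(annotated, cfg.support_threshold,
                                        assume_unsupported=100.0)
        (out / "collapsed.nwk").write_text(collapsed.to_newick(support=True) + "\n")
        outputs["collapsed.nwk"] = _sha256(out / "collapsed.nwk")
        for char_path in cfg.characters:
            states_txt = read_character_tsv(Path(char_path).read_text())
            labels = sorted(set(states_txt.values()) - {"?"})
            char = MorphCharacter(
                name=Path(char_path).stem, states=labels,
                tip_assignments={t: (None if s == "?" else labels.index(s))
                                 for t, s in states_txt.items()},
            )
            ml_res = mk_asr_ml(collapsed, char)
            mp_res = fitch_asr_mp(collapsed, char)
            p = out / f"asr_{char.name}_ml.tsv"
            p.write_text(ml_res.report_tsv())
            outputs[p.name] = _sha256(p)
            p = out / f"asr_{char.name}_mp.tsv"
            p.write_text(mp_res.report_tsv())
            outputs[p.name] = _sha256(p)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "strucphy_version": __version__,
        "config": {k: v for k, v in vars(cfg).items()},
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
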