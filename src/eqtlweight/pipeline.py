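"""End-to-end orchestration: weights -> weighted adjustment -> novelty report.

``run_pipeline`` reproduces the full reanalysis flow on any compatible
inputs: read an association table and an eQTL reference, build unweighted /
general / binary weight schemes, apply Bonferroni, Holm and BH at the
requested level (optionally with an effective test count), and emit per
scheme x method: a rejection report, a rank-shift table, a Q-Q table, and --
when an LD table is supplied -- an LD-aware novelty report of weighted-only
hits.  A manifest records every parameter so each number is regenerable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .io import (
    AssocTable,
    ColumnMap,
    EqtlTable,
    LdTable,
    read_assoc_table,
    read_eqtl_table,
    read_ld_table,
    write_table,
)
from .ld import novel_hits
from .multitest import (
    effective_test_count,
    qq_table,
    rank_shift_table,
    weighted_bh,
    weighted_bonferroni,
    weighted_holm,
    weighted_pvalues,
)
from .weights import (
    BinaryWeightParams,
    WeightVector,
    binary_weights,
    general_weights,
    normalize_weights,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    assoc_path: str
    eqtl_path: str
    output_dir: str
    ld_path: str | None = None
    dialect: str = "whitespace"
    alpha: float = 0.05
    methods: tuple[str, ...] = ("bonferroni", "holm", "bh")
    schemes: tuple[str, ...] = ("unweighted", "general", "binary")
    effective_ratio: float | None = None
    binary_epsilon: float = 0.106
    binary_up_weight: float = 3.70
    novelty_r2: float = 0.4
    seed: int | None = None

    def __post_init__(self) -> None:
        for name, v in (("alpha", self.alpha), ("novelty_r2", self.novelty_r2)):
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.effective_ratio is not None and not 0 < self.effective_ratio <= 1:
            raise ValueError("effective_ratio must lie in (0, 1]")


def _build_weights(
    scheme: str, assoc: AssocTable, eqtl: EqtlTable, cfg: RunConfig
) -> WeightVector:
    if scheme == "unweighted":
        return WeightVector(assoc.snp_ids.copy(), np.ones(assoc.m), normalized=True)
    if scheme == "general":
        return normalize_weights(general_weights(assoc, eqtl))
    if scheme == "binary":
        flags = np.isin(assoc.snp_ids, eqtl.snp_ids)
        params = BinaryWeightParams.from_up_weight(cfg.binary_epsilon, cfg.binary_up_weight)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return binary_weights(assoc, flags, params, renormalize=True)
    raise ValueError(f"unknown weight scheme {scheme!r}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full weighted-testing flow; returns a manifest of outputs."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    assoc = read_assoc_table(cfg.assoc_path, dialect=cfg.dialect)
    eqtl = read_eqtl_table(cfg.eqtl_path)
    ld = read_ld_table(cfg.ld_path) if cfg.ld_path else None

    count = (
        effective_test_count(assoc.m, cfg.effective_ratio)
        if cfg.effective_ratio is not None
        else None
    )
    flags = np.isin(assoc.snp_ids, eqtl.snp_ids)

    outputs: dict[str, str] = {}
    rejections: dict[tuple[str, str], list[str]] = {}
    n_rejected: dict[str, dict[str, int]] = {}
    for scheme in cfg.schemes:
        wv = _build_weights(scheme, assoc, eqtl, cfg)
        qt = weighted_pvalues(assoc, wv)
        rank_path = out / f"rank_shift_{scheme}.tsv"
        write_table(rank_shift_table(assoc, qt, flags), rank_path)
        outputs[f"rank_shift_{scheme}"] = str(rank_path)
        qq_path = out / f"qq_{scheme}.tsv"
        write_table(qq_table(qt), qq_path)
        outputs[f"qq_{scheme}"] = str(qq_path)
        n_rejected[scheme] = {}
        for method in cfg.methods:
            if method == "bonferroni":
                rep = weighted_bonferroni(qt, cfg.alpha, count)
            elif method == "holm":
                rep = weighted_holm(assoc, wv, cfg.alpha, count)
            elif method == "bh":
                rep = weighted_bh(qt, cfg.alpha, count)
            else:
                raise ValueError(f"unknown method {method!r}")
            path = out / f"rejections_{scheme}_{method}.tsv"
            write_table(rep.table, path)
            outputs[f"rejections_{scheme}_{method}"] = str(path)
            rejections[(scheme, method)] = rep.rejected
            n_rejected[scheme][method] = rep.n_rejected

    if ld is not None:
        for method in cfg.methods:
            base = set(rejections.get(("unweighted", method), []))
            for scheme in cfg.schemes:
                if scheme == "unweighted":
                    continue
                extra = set(rejections.get((scheme, method), []))
                report = novel_hits(extra, base, ld, r2=cfg.novelty_r2)
                path = out / f"novel_{scheme}_{method}.tsv"
                write_table(report.table, path)
                outputs[f"novel_{scheme}_{method}"] = str(path)

    manifest = {
        "eqtlweight_version": __version__,
        "config": asdict(cfg),
        "m": assoc.m,
        "effective_count": count,
        "n_eqtl_flagged": int(flags.sum()),
        "n_rejected": n_rejected,
        "outputs": outputs,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    outputs["manifest"] = str(manifest_path)
    return manifest
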