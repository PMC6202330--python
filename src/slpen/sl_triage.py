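"""Triage of candidate synthetic-lethal effects and penetrance scoring.

After per-gene association testing, candidate effects are filtered in
the order the analysis workflow runs:

1. keep genes with association p below ``p_cut`` (raw p, by design —
   BH q is reported but never gates);
2. drop effects whose median score in the defective group is above
   ``median_def_max`` (no profound inhibition where it matters);
3. drop effects whose median score in the not-altered group is below
   ``median_not_min`` (pan-lethal: profound inhibition everywhere);
4. score synthetic-lethal penetrance (SLP) — the percentage of
   defective lines with score strictly below ``sens_z_cut``;
5. score synthetic-lethal coverage (SLC) — the percentage of all
   sensitive lines (score below the same cut) that are defective —
   and call hits at SLP strictly above ``slp_cut_pct``.

All threshold comparisons are strict, exactly as the rules are printed
(median_def > -1 removed, median_not < -2 removed, SLP > 80 required);
boundary values are unit-tested. A line missing for a gene is excluded
from that gene's medians, SLP denominator and sensitivity counts,
never imputed. SLC with no sensitive line is *undefined* (serialised
NA): an empty denominator is information, not 0% or 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import RESULT_COLUMNS, GeneScoreMatrix
from .rb_classify import DEFECTIVE, NOT_ALTERED, StatusCall
from .sl_association import (
    DEFAULT_N_PERM,
    AssociationResult,
    association_frame,
    run_mp_screen,
)


@dataclass
class PipelineConfig:
    """Thresholds and settings for the end-to-end screen analysis.

    Defaults mirror the published workflow: p < 0.05 association gate,
    median-Z filters at -1 (defective) and -2 (not altered), line
    sensitivity at Z < -1, hit penetrance at SLP > 80%, one million
    permutations.
    """

    p_cut: float = 0.05
    median_def_max: float = -1.0
    median_not_min: float = -2.0
    sens_z_cut: float = -1.0
    slp_cut_pct: float = 80.0
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0
    side: str = "less"
    use_q_gate: bool = False  # optional FDR gate; the published choice is raw p

    def __post_init__(self) -> None:
        if not 0 < self.p_cut < 1:
            raise ValueError("p_cut must be in (0, 1)")
        if not (self.median_not_min < self.sens_z_cut <= 0):
            warnings.warn(
                "expected ordering median_not_min < sens_z_cut <= 0 violated "
                f"({self.median_not_min} vs {self.sens_z_cut})",
                stacklevel=2,
            )


@dataclass
class TriageResult:
    gene_id: str
    median_def: float
    median_not: float
    pass_p: bool
    pass_median_def: bool
    pass_median_not: bool


@dataclass
class PenetranceResult:
    gene_id: str
    slp_pct: float
    slc_pct: Optional[float]  # None iff no line is sensitive
    n_def_sensitive: int
    n_def_total: int
    n_sensitive_total: int
    hit: bool = False


def _clean(scores) -> np.ndarray:
    a = np.asarray(scores, dtype=float)
    return a[~np.isnan(a)]


def median_z_filter(
    scores_def: Sequence[float],
    scores_not: Sequence[float],
    config: PipelineConfig = PipelineConfig(),
    p: Optional[float] = None,
    gene_id: str = "",
) -> TriageResult:
    """Apply the two median-Z triage rules to one gene.

    ``pass_median_def`` is False iff the defective-group median is
    strictly above ``median_def_max`` (effect not profound where the
    biomarker is present); ``pass_median_not`` is False iff the
    not-altered median is strictly below ``median_not_min``
    (pan-lethal). ``pass_p`` evaluates p < p_cut when p is given.
    """
    d = _clean(scores_def)
    n = _clean(scores_not)
    if d.size == 0 or n.size == 0:
        raise ValueError("median_z_filter requires >=1 non-missing score per group")
    median_def = float(np.median(d))
    median_not = float(np.median(n))
    return TriageResult(
        gene_id=gene_id,
        median_def=median_def,
        median_not=median_not,
        pass_p=bool(p < config.p_cut) if p is not None and not np.isnan(p) else False,
        pass_median_def=not median_def > config.median_def_max,
        pass_median_not=not median_not < config.median_not_min,
    )


def compute_slp(scores_def: Sequence[float], sens_z_cut: float = -1.0) -> float:
    """Synthetic-lethal penetrance: % of defective lines scoring
    strictly below the sensitivity cut. Missing scores are excluded
    from numerator and denominator."""
    d = _clean(scores_def)
    if d.size == 0:
        raise ValueError("compute_slp requires >=1 non-missing defective score")
    return 100.0 * float(np.count_nonzero(d < sens_z_cut)) / d.size


def compute_slc(
    scores_def: Sequence[float],
    scores_not: Sequence[float],
    sens_z_cut: float = -1.0,
) -> Optional[float]:
    """Synthetic-lethal coverage: % of all sensitive lines (score below
    the cut, either group) that are defective. Undefined (None) when no
    line is sensitive."""
    d = _clean(scores_def)
    n = _clean(scores_not)
    if d.size == 0 and n.size == 0:
        raise ValueError("compute_slc requires non-empty score lists")
    n_def_sens = int(np.count_nonzero(d < sens_z_cut))
    n_sens = n_def_sens + int(np.count_nonzero(n < sens_z_cut))
    if n_sens == 0:
        return None
    return 100.0 * n_def_sens / n_sens


def penetrance_for_gene(
    scores_def: Sequence[float],
    scores_not: Sequence[float],
    config: PipelineConfig = PipelineConfig(),
    gene_id: str = "",
) -> PenetranceResult:
    """SLP + SLC + counts for one gene; ``hit`` is left False for the
    penetrance gate to set."""
    d = _clean(scores_def)
    n = _clean(scores_not)
    slp = compute_slp(d, config.sens_z_cut)
    slc = compute_slc(d, n, config.sens_z_cut)
    n_def_sens = int(np.count_nonzero(d < config.sens_z_cut))
    n_sens = n_def_sens + int(np.count_nonzero(n < config.sens_z_cut))
    return PenetranceResult(
        gene_id=gene_id,
        slp_pct=slp,
        slc_pct=slc,
        n_def_sensitive=n_def_sens,
        n_def_total=int(d.size),
        n_sensitive_total=n_sens,
    )


def apply_penetrance_filter(
    results: Sequence[PenetranceResult],
    config: PipelineConfig = PipelineConfig(),
) -> list[PenetranceResult]:
    """Set ``hit`` = True iff SLP strictly exceeds the cut; order preserved."""
    out = []
    for r in results:
        out.append(
            PenetranceResult(
                gene_id=r.gene_id,
                slp_pct=r.slp_pct,
                slc_pct=r.slc_pct,
                n_def_sensitive=r.n_def_sensitive,
                n_def_total=r.n_def_total,
                n_sensitive_total=r.n_sensitive_total,
                hit=r.slp_pct > config.slp_cut_pct,
            )
        )
    return out


def run_pipeline(
    matrix: GeneScoreMatrix,
    calls: Sequence[StatusCall],
    config: PipelineConfig = PipelineConfig(),
    associations: Optional[Sequence[AssociationResult]] = None,
) -> pd.DataFrame:
    """End-to-end screen analysis: association, triage, penetrance, hits.

    Returns one row per gene in matrix order with every intermediate
    statistic and per-filter flag, so each removal is attributable to
    the named filter(s). ``hit`` requires: tested, p < p_cut, both
    median filters passed, and SLP > slp_cut_pct. Pre-computed
    association results may be passed to skip the permutation stage.
    """
    status = {c.sample_id: c.status for c in calls}
    def_lines = [l for l in matrix.line_ids if status.get(l) == DEFECTIVE]
    not_lines = [l for l in matrix.line_ids if status.get(l) == NOT_ALTERED]
    if len(def_lines) < 2 or len(not_lines) < 2:
        raise ValueError(
            f"need >=2 lines per status group (got {len(def_lines)} defective, "
            f"{len(not_lines)} not altered)"
        )
    if associations is None:
        associations = run_mp_screen(
            matrix, calls, n_perm=config.n_perm, seed=config.seed, side=config.side
        )
    assoc = association_frame(associations).set_index("gene")

    rows = []
    for gene in matrix.gene_ids:
        a = assoc.loc[gene]
        row = {
            "gene": gene,
            "n_def": int(a["n_def"]),
            "n_not": int(a["n_not"]),
            "median_def": a["median_def"],
            "median_not": a["median_not"],
            "diff": a["diff"],
            "p": a["p"],
            "q": a["q"],
            "pass_p": False,
            "pass_median_def": False,
            "pass_median_not": False,
            "slp": np.nan,
            "slc": np.nan,
            "hit": False,
        }
        gate_p = a["q"] if config.use_q_gate else a["p"]
        if bool(a["tested"]) and not np.isnan(gate_p) and gate_p < config.p_cut:
            row["pass_p"] = True
            d = matrix.scores.loc[gene, def_lines].to_numpy(dtype=float)
            n = matrix.scores.loc[gene, not_lines].to_numpy(dtype=float)
            try:
                triage = median_z_filter(d, n, config, p=a["p"], gene_id=gene)
            except ValueError as exc:
                raise ValueError(f"gene {gene!r}: {exc}") from exc
            row["pass_median_def"] = triage.pass_median_def
            row["pass_median_not"] = triage.pass_median_not
            if triage.pass_median_def and triage.pass_median_not:
                pen = apply_penetrance_filter(
                    [penetrance_for_gene(d, n, config, gene_id=gene)], config
                )[0]
                row["slp"] = pen.slp_pct
                row["slc"] = np.nan if pen.slc_pct is None else pen.slc_pct
                row["hit"] = pen.hit
        rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
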