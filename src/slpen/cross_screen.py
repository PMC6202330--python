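"""Cross-screen concordance and stratified re-analysis.

Independently derived dependency screens (different libraries,
different scoring schemes) that converge on the same gene provide
reagent-independent evidence for a synthetic-lethal effect.
``intersect_significant`` finds genes called in at least ``min_screens``
screens; ``stratify_by_group`` repeats the association and penetrance
analysis within histology (or other) strata of one screen.

Gene identity across screens is by upper-cased symbol string — no
alias resolution. The Fisher combined p is descriptive ordering only,
never a hit criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .io_formats import GeneScoreMatrix
from .rb_classify import DEFECTIVE, NOT_ALTERED, StatusCall
from .sl_association import AssociationResult, mp_test
from .sl_triage import PenetranceResult, PipelineConfig, penetrance_for_gene


@dataclass
class ScreenResultSet:
    """One screen's per-gene result table plus identity metadata."""

    screen_id: str
    results: pd.DataFrame  # canonical result-table columns
    score_kind: str = "generic_z"


def intersect_significant(
    sets: Sequence[ScreenResultSet],
    min_screens: int = 2,
    use_hit_flag: bool = True,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Genes significant in at least ``min_screens`` screens.

    ``use_hit_flag=True`` requires the full-pipeline hit flag per
    screen; ``False`` uses raw p < p_cut alone. Output rows carry the
    supporting screens and per-screen p and SLP, ordered by number of
    screens (descending) then Fisher combined p (descending evidence).
    """
    if len(sets) < 2:
        raise ValueError("need at least two result sets to intersect")
    ids = [s.screen_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate screen ids: {ids}")
    per_screen: dict[str, dict[str, dict]] = {}
    for s in sets:
        df = s.results
        if use_hit_flag:
            sig = df[df["hit"].fillna(False).astype(bool)]
        else:
            sig = df[df["p"].notna() & (df["p"] < p_cut)]
        for r in sig.itertuples(index=False):
            gene = str(r.gene).upper()
            per_screen.setdefault(gene, {})[s.screen_id] = {
                "p": float(r.p),
                "slp": float(r.slp) if not pd.isna(r.slp) else np.nan,
            }
    rows = []
    for gene, hits in per_screen.items():
        if len(hits) < min_screens:
            continue
        ps = [v["p"] for v in hits.values()]
        combined = st.combine_pvalues(ps, method="fisher")[1] if len(ps) > 1 else ps[0]
        row = {
            "gene": gene,
            "n_screens": len(hits),
            "screens": ";".join(sorted(hits)),
            "combined_p": float(combined),
        }
        for sid in ids:
            row[f"p_{sid}"] = hits.get(sid, {}).get("p", np.nan)
            row[f"slp_{sid}"] = hits.get(sid, {}).get("slp", np.nan)
        rows.append(row)
    out = pd.DataFrame(
        rows,
        columns=["gene", "n_screens", "screens", "combined_p"]
        + [c for sid in ids for c in (f"p_{sid}", f"slp_{sid}")],
    )
    if len(out):
        out = out.sort_values(
            ["n_screens", "combined_p"], ascending=[False, True]
        ).reset_index(drop=True)
    return out


def stratify_by_group(
    matrix: GeneScoreMatrix,
    calls: Sequence[StatusCall],
    groups: Mapping[str, str],
    gene_id: str,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Per-stratum association + penetrance for one gene.

    Within each label's lines the MP test and SLP/SLC are recomputed.
    Strata with a single defective line (or a single not-altered line)
    are reported descriptively — medians and SLP shown, p = NaN —
    and strata with no defective line are marked untestable.
    """
    if gene_id not in matrix.scores.index:
        raise KeyError(f"gene {gene_id!r} not in matrix")
    status = {c.sample_id: c.status for c in calls}
    scores = matrix.row(gene_id)
    labels = sorted({groups[l] for l in matrix.line_ids if l in groups})
    rows = []
    for label in labels:
        lines = [l for l in matrix.line_ids if groups.get(l) == label]
        d = scores[[l for l in lines if status.get(l) == DEFECTIVE]].dropna()
        n = scores[[l for l in lines if status.get(l) == NOT_ALTERED]].dropna()
        row = {
            "group": label,
            "gene": gene_id,
            "n_def": int(d.size),
            "n_not": int(n.size),
            "median_def": float(np.median(d)) if d.size else np.nan,
            "median_not": float(np.median(n)) if n.size else np.nan,
            "p": np.nan,
            "slp": np.nan,
            "slc": np.nan,
            "testable": False,
        }
        if d.size >= 1:
            row["slp"] = compute_slp_safe(d.to_numpy(), config.sens_z_cut)
            if n.size >= 1:
                from .sl_triage import compute_slc

                slc = compute_slc(d.to_numpy(), n.to_numpy(), config.sens_z_cut)
                row["slc"] = np.nan if slc is None else slc
        if d.size >= 2 and n.size >= 2:
            res = mp_test(
                d.to_numpy(),
                n.to_numpy(),
                n_perm=config.n_perm,
                seed=config.seed,
                side=config.side,
            )
            row["p"] = res.p
            row["testable"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def compute_slp_safe(scores_def, sens_z_cut: float) -> float:
    from .sl_triage import compute_slp

    try:
        return compute_slp(scores_def, sens_z_cut)
    except ValueError:
        return float("nan")
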