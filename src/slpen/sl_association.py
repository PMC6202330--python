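"""Per-gene association between biomarker status and depletion scores.

Three routes from a dependency screen to per-gene significance:

* **zGARP-style aggregation** — a gene's depletion in one line is
  summarised as the mean of its two most-depleted hairpins, then
  Z-normalised across the screen (``aggregate_hairpins_to_gene``,
  ``z_normalize_gene_scores``).

* **Median-permutation (MP) test** — the observed difference between
  the group medians (defective minus not-altered) is compared with the
  differences obtained under random reassignment of group labels at the
  same group sizes. One-sided: ``side='less'`` asks whether defective
  lines are more depleted (the synthetic-lethal direction);
  ``side='greater'`` the dependency-of-proficient direction. The
  Monte-Carlo p uses the add-one estimator (b+1)/(N+1), never zero;
  the exhaustive oracle ``mp_test_exact`` enumerates every assignment
  and uses b/N. Ties in permuted differences count toward b.

* **Dropout-trend test** — for hairpin-level time courses, a two-stage
  approximation of a hierarchical mixed-effect dropout model: per
  (hairpin, line) OLS slopes of log-abundance over time, then slopes
  modelled as mean + group effect + hairpin random intercept (REML).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneScoreMatrix
from .rb_classify import DEFECTIVE, NOT_ALTERED, StatusCall

#: default number of random label reassignments for the MP test
DEFAULT_N_PERM = 1_000_000

#: permutations processed per block (bounds peak memory at ~tens of MB)
_PERM_BLOCK = 200_000

#: gene x permutation cells processed per chunk in the screen runner
_SCREEN_CELLS = 20_000_000


@dataclass
class AssociationResult:
    gene_id: str
    n_def: int
    n_not: int
    median_def: float
    median_not: float
    diff: float
    p: float
    q: float = float("nan")
    tested: bool = True


@dataclass
class TrendModel:
    """Fitted group-difference in dropout slope for one gene."""

    gene_id: str
    beta_group_trend: float
    se: float
    p: float  # one-sided, in the requested SL direction
    n_hairpins: int
    method: str  # 'mixed' or 'ols'


# ---------------------------------------------------------------------------
# hairpin aggregation and normalisation
# ---------------------------------------------------------------------------

def aggregate_hairpins_to_gene(hairpin_scores: Mapping[str, float] | Sequence[float]) -> float:
    """Gene-level depletion summary: mean of the two lowest hairpin scores.

    With a single hairpin, that score. Permutation-invariant in its
    input and monotone: lowering either of the two lowest scores never
    raises the output.
    """
    if isinstance(hairpin_scores, Mapping):
        values = np.asarray(list(hairpin_scores.values()), dtype=float)
    else:
        values = np.asarray(list(hairpin_scores), dtype=float)
    if values.size == 0:
        raise ValueError("no hairpin scores supplied")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite hairpin score")
    if values.size == 1:
        return float(values[0])
    lowest_two = np.partition(values, 1)[:2]
    return float(lowest_two.mean())


def z_normalize_gene_scores(matrix: GeneScoreMatrix, axis: str = "per_gene") -> GeneScoreMatrix:
    """Standardise scores to mean 0, sample SD 1 along genes or lines.

    Missing entries are preserved and excluded from the moments. A
    vector with fewer than two observed values or zero spread is an
    error naming the offending gene or line.
    """
    if axis not in {"per_gene", "per_line"}:
        raise ValueError(f"axis must be 'per_gene' or 'per_line', got {axis!r}")
    df = matrix.scores
    work = df if axis == "per_gene" else df.T
    n = work.notna().sum(axis=1)
    if (n < 2).any():
        bad = work.index[n < 2].tolist()
        raise ValueError(f"fewer than 2 non-missing values for: {bad}")
    mean = work.mean(axis=1)
    sd = work.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = work.index[sd == 0].tolist()
        raise ValueError(f"zero spread (cannot standardise): {bad}")
    out = work.sub(mean, axis=0).div(sd, axis=0)
    if axis == "per_line":
        out = out.T
    return GeneScoreMatrix(out, matrix.score_kind)


# ---------------------------------------------------------------------------
# median-permutation test
# ---------------------------------------------------------------------------

def _clean_groups(scores_def, scores_not, min_per_group: int = 2):
    d = np.asarray(scores_def, dtype=float)
    n = np.asarray(scores_not, dtype=float)
    d = d[~np.isnan(d)]
    n = n[~np.isnan(n)]
    if d.size < min_per_group or n.size < min_per_group:
        raise ValueError(
            f"need >= {min_per_group} non-missing scores per group "
            f"(got {d.size} defective, {n.size} not-altered)"
        )
    return d, n


def _permuted_median_diffs(pooled: np.ndarray, n_def: int, n_perm: int, rng: np.random.Generator):
    """Yield blocks of median differences under random label reassignment."""
    n = pooled.size
    done = 0
    while done < n_perm:
        block = min(_PERM_BLOCK, n_perm - done)
        idx = np.argsort(rng.random((block, n)), axis=1)
        sampled = pooled[idx]
        diffs = np.median(sampled[:, :n_def], axis=1) - np.median(sampled[:, n_def:], axis=1)
        yield diffs
        done += block


def mp_test(
    scores_def: Sequence[float],
    scores_not: Sequence[float],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    side: str = "less",
    gene_id: str = "",
) -> AssociationResult:
    """One-sided median-permutation test for one gene.

    The observed statistic is median(defective) - median(not altered).
    ``n_perm`` random label reassignments at the observed group sizes
    form the reference; p = (b + 1) / (n_perm + 1) where b counts
    permuted differences <= observed (``side='less'``) or >= observed
    (``side='greater'``), ties inclusive.
    """
    if side not in {"less", "greater"}:
        raise ValueError(f"side must be 'less' or 'greater', got {side!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    d, nt = _clean_groups(scores_def, scores_not)
    median_def = float(np.median(d))
    median_not = float(np.median(nt))
    diff = median_def - median_not
    pooled = np.concatenate([d, nt])
    rng = np.random.default_rng(seed)
    b = 0
    for diffs in _permuted_median_diffs(pooled, d.size, n_perm, rng):
        b += int(np.count_nonzero(diffs <= diff if side == "less" else diffs >= diff))
    p = (b + 1) / (n_perm + 1)
    return AssociationResult(
        gene_id=gene_id,
        n_def=int(d.size),
        n_not=int(nt.size),
        median_def=median_def,
        median_not=median_not,
        diff=diff,
        p=float(p),
    )


def mp_test_exact(
    scores_def: Sequence[float],
    scores_not: Sequence[float],
    side: str = "less",
    max_total: int = 20,
) -> float:
    """Exhaustive-enumeration oracle for the MP test.

    Enumerates every distinct assignment of the pooled scores into two
    groups of the observed sizes; p = b / C(n, n_def) with the observed
    assignment included in the count (so p is never zero and needs no
    add-one correction).
    """
    if side not in {"less", "greater"}:
        raise ValueError(f"side must be 'less' or 'greater', got {side!r}")
    d, nt = _clean_groups(scores_def, scores_not, min_per_group=1)
    n = d.size + nt.size
    if n > max_total:
        raise ValueError(f"enumeration infeasible: {n} > {max_total} total scores")
    pooled = np.concatenate([d, nt])
    diff = float(np.median(d) - np.median(nt))
    total = comb(n, d.size)
    b = 0
    all_idx = frozenset(range(n))
    for def_idx in combinations(range(n), d.size):
        not_idx = list(all_idx - set(def_idx))
        delta = float(np.median(pooled[list(def_idx)]) - np.median(pooled[not_idx]))
        if (delta <= diff) if side == "less" else (delta >= diff):
            b += 1
    return b / total


def _pattern_seed(base_seed: int, line_ids: Iterable[str]) -> int:
    """Deterministic sub-seed for one missingness pattern.

    Keyed on the sorted set of present line ids, so genes sharing a
    pattern share a permutation stream and the result is invariant to
    cell-line column order.
    """
    key = repr((int(base_seed), tuple(sorted(map(str, line_ids)))))
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


def run_mp_screen(
    matrix: GeneScoreMatrix,
    calls: Sequence[StatusCall],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    side: str = "less",
) -> list[AssociationResult]:
    """MP test for every gene in a screen.

    Lines are matched to status calls by id; unclassifiable lines are
    ignored. Genes sharing a missingness pattern (the same set of
    scored lines) share a single seeded permutation stream; genes with
    fewer than two scores in either group are reported untested with
    p = NaN rather than dropped. Benjamini-Hochberg q-values are
    appended over all tested genes (reporting only — hit-calling uses
    raw p downstream).
    """
    status = {c.sample_id: c.status for c in calls}
    def_lines = sorted(l for l in matrix.line_ids if status.get(l) == DEFECTIVE)
    not_lines = sorted(l for l in matrix.line_ids if status.get(l) == NOT_ALTERED)
    if not def_lines:
        raise ValueError("no defective lines among the matrix columns")
    if not not_lines:
        raise ValueError("no not-altered lines among the matrix columns")

    def_scores = matrix.scores[def_lines].to_numpy(dtype=float)
    not_scores = matrix.scores[not_lines].to_numpy(dtype=float)
    genes = matrix.gene_ids
    n_genes = len(genes)

    results: dict[int, AssociationResult] = {}
    # group genes by missingness pattern over the ordered (def + not) lines
    pattern_members: dict[tuple, list[int]] = {}
    for gi in range(n_genes):
        dmask = ~np.isnan(def_scores[gi])
        nmask = ~np.isnan(not_scores[gi])
        if dmask.sum() < 2 or nmask.sum() < 2:
            d = def_scores[gi][dmask]
            nt = not_scores[gi][nmask]
            results[gi] = AssociationResult(
                gene_id=genes[gi],
                n_def=int(dmask.sum()),
                n_not=int(nmask.sum()),
                median_def=float(np.median(d)) if d.size else float("nan"),
                median_not=float(np.median(nt)) if nt.size else float("nan"),
                diff=float("nan"),
                p=float("nan"),
                tested=False,
            )
            continue
        pattern_members.setdefault(
            (tuple(np.flatnonzero(dmask)), tuple(np.flatnonzero(nmask))), []
        ).append(gi)

    for (didx, nidx), members in pattern_members.items():
        present_ids = [def_lines[i] for i in didx] + [not_lines[i] for i in nidx]
        rng = np.random.default_rng(_pattern_seed(seed, present_ids))
        n_def, n_not = len(didx), len(nidx)
        n = n_def + n_not
        D = def_scores[np.ix_(members, list(didx))]
        N = not_scores[np.ix_(members, list(nidx))]
        med_def = np.median(D, axis=1)
        med_not = np.median(N, axis=1)
        obs = med_def - med_not
        pooled = np.hstack([D, N])  # genes x n, pattern-complete
        b = np.zeros(len(members), dtype=np.int64)
        gene_chunk = max(1, _SCREEN_CELLS // max(1, _PERM_BLOCK * n))
        done = 0
        while done < n_perm:
            block = min(_PERM_BLOCK, n_perm - done)
            idx = np.argsort(rng.random((block, n)), axis=1)
            for lo in range(0, len(members), gene_chunk):
                hi = min(lo + gene_chunk, len(members))
                sampled = pooled[lo:hi][:, idx]  # (chunk, block, n)
                diffs = np.median(sampled[:, :, :n_def], axis=2) - np.median(
                    sampled[:, :, n_def:], axis=2
                )
                if side == "less":
                    b[lo:hi] += np.count_nonzero(diffs <= obs[lo:hi, None], axis=1)
                else:
                    b[lo:hi] += np.count_nonzero(diffs >= obs[lo:hi, None], axis=1)
            done += block
        p = (b + 1) / (n_perm + 1)
        for k, gi in enumerate(members):
            results[gi] = AssociationResult(
                gene_id=genes[gi],
                n_def=n_def,
                n_not=n_not,
                median_def=float(med_def[k]),
                median_not=float(med_not[k]),
                diff=float(obs[k]),
                p=float(p[k]),
            )

    ordered = [results[gi] for gi in range(n_genes)]
    tested = [r for r in ordered if r.tested]
    if tested:
        q = multipletests([r.p for r in tested], method="fdr_bh")[1]
        for r, qv in zip(tested, q):
            r.q = float(qv)
    return ordered


def association_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Tabulate association results (one row per gene, input order)."""
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in results],
            "n_def": [r.n_def for r in results],
            "n_not": [r.n_not for r in results],
            "median_def": [r.median_def for r in results],
            "median_not": [r.median_not for r in results],
            "diff": [r.diff for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "tested": [r.tested for r in results],
        }
    )


# ---------------------------------------------------------------------------
# dropout-trend test (two-stage mixed-model approximation)
# ---------------------------------------------------------------------------

def fit_dropout_slopes(timecourse: pd.DataFrame) -> pd.DataFrame:
    """Stage 1: OLS slope of log-abundance over time per (hairpin, line).

    ``timecourse`` columns: hairpin_id, gene_id, line_id, time,
    log_abundance. Series with fewer than two distinct time points are
    an error listing the offending hairpins.
    """
    required = {"hairpin_id", "line_id", "time", "log_abundance"}
    missing = required - set(timecourse.columns)
    if missing:
        raise ValueError(f"time course missing columns: {sorted(missing)}")
    bad = []
    rows = []
    for (hp, line), grp in timecourse.groupby(["hairpin_id", "line_id"], sort=True):
        t = grp["time"].to_numpy(dtype=float)
        y = grp["log_abundance"].to_numpy(dtype=float)
        if np.unique(t).size < 2:
            bad.append(str(hp))
            continue
        slope = np.polyfit(t, y, 1)[0]
        rows.append({"hairpin_id": hp, "line_id": line, "slope": float(slope)})
    if bad:
        raise ValueError(f"fewer than 2 distinct time points for hairpins: {sorted(set(bad))}")
    return pd.DataFrame(rows)


def trend_test(
    timecourse: pd.DataFrame,
    calls: Sequence[StatusCall],
    side: str = "less",
    gene_id: Optional[str] = None,
) -> TrendModel:
    """Group difference in dropout slope for one gene's time course.

    Stage 2 models the per-(hairpin, line) slopes as
    ``slope = mu + gamma * defective + hairpin random intercept + noise``
    fitted by REML; ``beta_group_trend`` is the estimated gamma, with a
    Wald p halved into the requested one-sided direction. With a single
    hairpin the random intercept is unidentifiable and the model
    reduces to OLS of slopes on group (equal-variance t test).
    """
    if side not in {"less", "greater"}:
        raise ValueError(f"side must be 'less' or 'greater', got {side!r}")
    if gene_id is None:
        gene_id = str(timecourse["gene_id"].iloc[0]) if "gene_id" in timecourse.columns else ""
    status = {c.sample_id: c.status for c in calls}
    slopes = fit_dropout_slopes(timecourse)
    slopes["group"] = slopes["line_id"].map(
        lambda l: 1.0 if status.get(l) == DEFECTIVE else (0.0 if status.get(l) == NOT_ALTERED else np.nan)
    )
    slopes = slopes.dropna(subset=["group"])
    n_hp = slopes["hairpin_id"].nunique()
    for label, g in (("defective", 1.0), ("not-altered", 0.0)):
        if slopes.loc[slopes["group"] == g, "line_id"].nunique() < 2:
            raise ValueError(f"fewer than 2 {label} lines with fitted slopes")

    y = slopes["slope"].to_numpy()
    X = sm.add_constant(slopes["group"].to_numpy())
    if n_hp >= 2:
        model = sm.MixedLM(y, X, groups=slopes["hairpin_id"].to_numpy())
        # a zero hairpin variance is a legitimate REML boundary solution
        # (fixed effects remain valid); silence the boundary chatter
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = model.fit(reml=True, method="lbfgs")
            beta = float(fit.fe_params[1])
            se = float(fit.bse_fe[1])
        if not np.isfinite(se) or se <= 0:
            # fully degenerate data (no residual variation): no evidence
            # against the null in either direction
            return TrendModel(
                gene_id=gene_id,
                beta_group_trend=beta,
                se=float("nan"),
                p=1.0,
                n_hairpins=int(n_hp),
                method="mixed",
            )
        p_two = 2 * st.norm.sf(abs(beta / se))
        method = "mixed"
    else:
        fit = sm.OLS(y, X).fit()
        beta = float(fit.params[1])
        se = float(fit.bse[1])
        p_two = float(fit.pvalues[1])
        method = "ols"
    if side == "less":
        p_one = p_two / 2 if beta < 0 else 1 - p_two / 2
    else:
        p_one = p_two / 2 if beta > 0 else 1 - p_two / 2
    # keep p in (0, 1]
    p_one = min(max(p_one, np.nextafter(0, 1)), 1.0)
    return TrendModel(
        gene_id=gene_id,
        beta_group_trend=beta,
        se=se,
        p=float(p_one),
        n_hairpins=int(n_hp),
        method=method,
    )
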