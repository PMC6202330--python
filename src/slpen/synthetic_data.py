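"""Ground-truth simulators for dependency screens and their annotations.

Generates the statistical structure the analysis assumes, with known
truth, so every pipeline stage is testable without downloading a
screen:

* gene x cell-line depletion matrices on the Z scale — null genes are
  standard normal per line; a planted synthetic-lethal gene is shifted
  by ``-delta`` in *carrier* lines (each defective line independently a
  carrier with probability ``pi``, the per-line penetrance); a planted
  pan-lethal gene is shifted in every line; missingness is completely
  at random;
* hairpin-level log-abundance time courses with a group difference in
  dropout slope (``gamma < 0`` encodes synthetic-lethal dropout);
* omics annotation tables that the status classifier maps back exactly
  onto the generating defective / not-altered split;
* the closed-form expected SLP under this generative model, the oracle
  the empirical penetrance estimates are checked against.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .io_formats import GeneScoreMatrix
from .rb_classify import (
    DEFECTIVE,
    NOT_ALTERED,
    ClassificationThresholds,
    StatusCall,
)


@dataclass(frozen=True)
class PlantedEffect:
    """A gene with a planted dependency: penetrance pi, effect size delta >= 0."""

    gene_id: str
    penetrance: float = 1.0
    effect: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.penetrance <= 1:
            raise ValueError("penetrance must be in [0, 1]")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")


@dataclass(frozen=True)
class TimecourseConfig:
    """Hairpin time-course block: dropout slopes mu (baseline) and
    mu + gamma (defective carriers), hairpin random-slope sd, residual
    noise sd, time grid in screen passages."""

    n_hairpins: int = 5
    times: tuple = (0.0, 1.0, 2.0, 3.0)
    mu: float = -0.1
    gamma: float = -0.5
    hairpin_sd: float = 0.1
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if len(set(self.times)) < 2:
            raise ValueError("need >= 2 distinct time points")
        if self.n_hairpins < 1:
            raise ValueError("need >= 1 hairpin")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated screen.

    Defaults emulate the triple-negative breast cancer panel the
    analysis was designed for: 42 cell lines of which 12 are
    biomarker-defective, unit-variance Z scores.
    """

    n_genes: int = 500
    n_lines: int = 42
    frac_defective: float = 12 / 42
    planted_sl: tuple = ()
    planted_panlethal: tuple = ()
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0
    timecourse: Optional[TimecourseConfig] = None

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_lines < 4:
            raise ValueError("need >= 1 gene and >= 4 lines")
        if not 0 < self.frac_defective < 1:
            raise ValueError("frac_defective must be in (0, 1)")
        if int(round(self.frac_defective * self.n_lines)) < 2:
            raise ValueError("frac_defective * n_lines must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        planted = [e.gene_id for e in self.planted_sl] + [
            e.gene_id for e in self.planted_panlethal
        ]
        if len(planted) != len(set(planted)):
            raise ValueError("planted gene ids must be unique")
        n_auto = self.n_genes - len(planted)
        if n_auto < 0:
            raise ValueError("more planted genes than n_genes")


def _gene_ids(config: SimulationConfig) -> list[str]:
    planted = [e.gene_id for e in config.planted_sl] + [
        e.gene_id for e in config.planted_panlethal
    ]
    nulls = [f"NULL{i:05d}" for i in range(config.n_genes - len(planted))]
    return planted + nulls


def simulate_gene_score_screen(
    config: SimulationConfig,
) -> tuple[GeneScoreMatrix, list[StatusCall], pd.DataFrame]:
    """Simulate a Z-scored dependency screen with planted effects.

    Returns the score matrix, per-line status calls, and a truth table
    with per-gene class (null / sl / panlethal), pi, delta, and the
    per-line carrier flags for each planted synthetic-lethal gene.
    """
    rng = np.random.default_rng(config.seed)
    n_def = int(round(config.frac_defective * config.n_lines))
    line_ids = [f"LINE{i:03d}" for i in range(config.n_lines)]
    defective = np.zeros(config.n_lines, dtype=bool)
    defective[rng.choice(config.n_lines, size=n_def, replace=False)] = True
    calls = [
        StatusCall(
            lid,
            DEFECTIVE if defective[i] else NOT_ALTERED,
            frozenset({"mrna_low"}) if defective[i] else frozenset(),
        )
        for i, lid in enumerate(line_ids)
    ]

    gene_ids = _gene_ids(config)
    scores = rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_lines))

    truth_rows = []
    carrier_cols = {}
    gi = 0
    for effect in config.planted_sl:
        carriers = defective & (rng.random(config.n_lines) < effect.penetrance)
        scores[gi, carriers] -= effect.effect
        carrier_cols[effect.gene_id] = carriers
        truth_rows.append(
            {"gene": effect.gene_id, "class": "sl", "pi": effect.penetrance, "delta": effect.effect}
        )
        gi += 1
    for effect in config.planted_panlethal:
        scores[gi, :] -= effect.effect
        carrier_cols[effect.gene_id] = np.ones(config.n_lines, dtype=bool)
        truth_rows.append(
            {"gene": effect.gene_id, "class": "panlethal", "pi": 1.0, "delta": effect.effect}
        )
        gi += 1
    for gene in gene_ids[gi:]:
        truth_rows.append({"gene": gene, "class": "null", "pi": 0.0, "delta": 0.0})

    if config.missing_rate > 0:
        mask = rng.random(scores.shape) < config.missing_rate
        scores = np.where(mask, np.nan, scores)

    matrix = GeneScoreMatrix(
        pd.DataFrame(scores, index=gene_ids, columns=line_ids), "generic_z"
    )
    truth = pd.DataFrame(truth_rows).set_index("gene")
    truth["n_def"] = n_def
    line_truth = pd.DataFrame({"defective": defective}, index=line_ids)
    for gene, carriers in carrier_cols.items():
        line_truth[f"carrier_{gene}"] = carriers
    truth.attrs["lines"] = line_truth
    return matrix, calls, truth


def simulate_hairpin_timecourse(
    config: SimulationConfig,
    gene_id: str = "SLGENE",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate hairpin log-abundance over time for one gene.

    Model per (hairpin h, line l):
    ``y(t) = a_h + (mu + gamma * defective_l * carrier_l + u_h) * t + eps``
    with hairpin random slope u_h ~ N(0, hairpin_sd^2) and residual
    eps ~ N(0, noise_sd^2). Carrier status follows the first planted
    synthetic-lethal effect's penetrance (default 1).
    """
    if config.timecourse is None:
        raise ValueError("config.timecourse block is required")
    tc = config.timecourse
    rng = np.random.default_rng(config.seed)
    n_def = int(round(config.frac_defective * config.n_lines))
    line_ids = [f"LINE{i:03d}" for i in range(config.n_lines)]
    defective = np.zeros(config.n_lines, dtype=bool)
    defective[rng.choice(config.n_lines, size=n_def, replace=False)] = True
    pi = config.planted_sl[0].penetrance if config.planted_sl else 1.0
    carriers = defective & (rng.random(config.n_lines) < pi)

    times = np.asarray(tc.times, dtype=float)
    u = rng.normal(0.0, tc.hairpin_sd, size=tc.n_hairpins)
    a = rng.normal(0.0, 0.5, size=tc.n_hairpins)  # hairpin baseline abundance
    records = []
    for h in range(tc.n_hairpins):
        hp = f"{gene_id}_hp{h}"
        for i, lid in enumerate(line_ids):
            slope = tc.mu + (tc.gamma if carriers[i] else 0.0) + u[h]
            y = a[h] + slope * times + rng.normal(0.0, tc.noise_sd, size=times.size)
            for t, yy in zip(times, y):
                records.append(
                    {
                        "hairpin_id": hp,
                        "gene_id": gene_id,
                        "line_id": lid,
                        "time": float(t),
                        "log_abundance": float(yy),
                    }
                )
    truth = pd.DataFrame(
        {"defective": defective, "carrier": carriers}, index=line_ids
    )
    return pd.DataFrame.from_records(records), truth


def status_calls_from_truth(truth: pd.DataFrame) -> list[StatusCall]:
    """Status calls for the lines of a time-course truth table."""
    return [
        StatusCall(
            str(lid),
            DEFECTIVE if bool(row.defective) else NOT_ALTERED,
            frozenset({"mrna_low"}) if bool(row.defective) else frozenset(),
        )
        for lid, row in truth.iterrows()
    ]


def simulate_omics_annotations(
    calls: Sequence[StatusCall],
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate omics values the classifier maps back onto ``calls``.

    Each defective sample receives at least one evidence field beyond
    its threshold (which ones is random); not-altered samples receive
    values on the safe side of every threshold. Round-trips exactly
    through the cell-line classifier.
    """
    if not calls:
        raise ValueError("calls must be non-empty")
    rng = np.random.default_rng(seed)
    cn_cut = abs(thresholds.cn_log2_cut)
    rows = []
    for call in calls:
        if call.status == DEFECTIVE:
            kinds = ["mrna_low", "cn_loss", "truncating_mutation", "protein_low"]
            chosen = set(
                rng.choice(kinds, size=rng.integers(1, len(kinds) + 1), replace=False)
            )
            row = {
                "sample_id": call.sample_id,
                "mrna_z": (
                    thresholds.mrna_z_cut - 0.2 - rng.exponential(1.0)
                    if "mrna_low" in chosen
                    else float(rng.uniform(thresholds.mrna_z_cut + 0.1, 2.0))
                ),
                "cn_log2": (
                    -cn_cut - 0.1 - rng.exponential(0.5)
                    if "cn_loss" in chosen
                    else float(rng.uniform(-cn_cut + 0.05, cn_cut - 0.05))
                ),
                "mutation": "truncating" if "truncating_mutation" in chosen
                else str(rng.choice(["none", "missense"])),
                "protein_low": "protein_low" in chosen,
            }
        else:
            row = {
                "sample_id": call.sample_id,
                "mrna_z": float(rng.uniform(thresholds.mrna_z_cut + 0.1, 2.0)),
                "cn_log2": float(rng.uniform(-cn_cut + 0.05, cn_cut - 0.05)),
                "mutation": str(rng.choice(["none", "missense"])),
                "protein_low": False,
            }
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def expected_slp(
    pi: float,
    delta: float,
    sigma: float = 1.0,
    sens_z_cut: float = -1.0,
) -> float:
    """Closed-form expected SLP under the simulation model.

    A defective line is a carrier with probability pi; carrier scores
    are N(-delta, sigma^2), non-carrier scores N(0, sigma^2), so

    ``E[SLP] = 100 * (pi * Phi((cut + delta) / sigma)
                      + (1 - pi) * Phi(cut / sigma))``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0 <= pi <= 1:
        raise ValueError("pi must be in [0, 1]")
    return 100.0 * (
        pi * st.norm.cdf((sens_z_cut + delta) / sigma)
        + (1 - pi) * st.norm.cdf(sens_z_cut / sigma)
    )
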