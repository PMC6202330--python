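"""Multi-omic classification of tumour-suppressor status.

Samples (tumours or cell lines) are called *defective* or *not altered*
for a target tumour suppressor (canonically RB1) from any-evidence OR
logic over: cohort-standardised mRNA Z score below a cut, copy-number
loss, a truncating mutation, and (cell lines only) low protein
expression. All thresholds are strict inequalities as printed in the
source rules: mRNA Z < -1, copy-number log2 ratio < -log2(3/2) for
loss; boundary values never trigger evidence.

Missense mutations never count as evidence. Protein-low status is
consumed as a pre-made boolean — no numeric western/iBAQ cutoff exists,
so deriving it is the caller's responsibility. Conflicting evidence
(e.g. low mRNA but protein present) resolves to defective: the rule is
"one or more defects".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

DEFECTIVE = "defective"
NOT_ALTERED = "not_altered"
UNCLASSIFIABLE = "unclassifiable"

MUTATION_LABELS = {"none", "missense", "truncating"}
CN_CALL_LABELS = {"gain", "neutral", "loss"}


@dataclass(frozen=True)
class ClassificationThresholds:
    """Strict-inequality evidence thresholds.

    mrna_z_cut: samples with target mRNA Z strictly below this are
        expression-low (default -1).
    cn_log2_cut: copy-number log2 ratios strictly below -|cut| are loss,
        strictly above +|cut| gain (default -log2(3/2) ~= -0.585).
    require_truncating: only truncating mutations count as evidence.
    """

    mrna_z_cut: float = -1.0
    cn_log2_cut: float = -math.log2(3 / 2)
    require_truncating: bool = True

    def __post_init__(self) -> None:
        if not self.mrna_z_cut < 0:
            raise ValueError("mrna_z_cut must be negative")
        if not self.cn_log2_cut < 0:
            raise ValueError("cn_log2_cut must be negative")


@dataclass(frozen=True)
class OmicsRecord:
    """Per-sample omics evidence for one target gene. Missing fields are None."""

    sample_id: str
    mrna_z: Optional[float] = None
    cn_log2: Optional[float] = None
    cn_call: Optional[str] = None  # pre-made call, Metabric style
    mutation: Optional[str] = None
    protein_low: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.mutation is not None and self.mutation not in MUTATION_LABELS:
            raise ValueError(f"unknown mutation label {self.mutation!r}")
        if self.cn_call is not None and self.cn_call not in CN_CALL_LABELS:
            raise ValueError(f"unknown cn_call label {self.cn_call!r}")


@dataclass(frozen=True)
class StatusCall:
    """Binary defective / not-altered call with the evidence that drove it."""

    sample_id: str
    status: str
    evidence: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.status not in {DEFECTIVE, NOT_ALTERED, UNCLASSIFIABLE}:
            raise ValueError(f"unknown status {self.status!r}")
        if (self.status == DEFECTIVE) != bool(self.evidence):
            raise ValueError("status defective iff evidence non-empty")


def copy_number_state(
    cn_log2: Optional[float],
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> Optional[str]:
    """Convert a copy-number log2 ratio to gain / neutral / loss.

    Strict comparisons at ±|cn_log2_cut|; a ratio exactly at the cut is
    neutral. Missing input yields missing output, never neutral.
    """
    if cn_log2 is None or (isinstance(cn_log2, float) and math.isnan(cn_log2)):
        return None
    if not math.isfinite(cn_log2):
        raise ValueError(f"non-finite copy-number log2 ratio: {cn_log2}")
    cut = abs(thresholds.cn_log2_cut)
    if cn_log2 < -cut:
        return "loss"
    if cn_log2 > cut:
        return "gain"
    return "neutral"


def _gather_evidence(
    record: OmicsRecord,
    thresholds: ClassificationThresholds,
    use_cn_log2: bool,
    use_cn_call: bool,
    use_protein: bool,
) -> tuple[set, bool]:
    """Return (evidence flags, any field observed)."""
    evidence: set = set()
    observed = False
    if record.mrna_z is not None and not math.isnan(record.mrna_z):
        observed = True
        if record.mrna_z < thresholds.mrna_z_cut:
            evidence.add("mrna_low")
    if use_cn_log2 and record.cn_log2 is not None and not (
        isinstance(record.cn_log2, float) and math.isnan(record.cn_log2)
    ):
        observed = True
        if copy_number_state(record.cn_log2, thresholds) == "loss":
            evidence.add("cn_loss")
    if use_cn_call and record.cn_call is not None:
        observed = True
        if record.cn_call == "loss":
            evidence.add("cn_loss")
    if record.mutation is not None:
        observed = True
        if record.mutation == "truncating" or (
            not thresholds.require_truncating and record.mutation == "missense"
        ):
            evidence.add("truncating_mutation")
    if use_protein and record.protein_low is not None:
        observed = True
        if record.protein_low:
            evidence.add("protein_low")
    return evidence, observed


def classify_tumour(
    record: OmicsRecord,
    rules: str = "tcga",
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> StatusCall:
    """Classify a tumour sample as defective / not altered.

    ``tcga`` rules use mRNA Z, copy-number log2 ratio and mutation;
    ``metabric`` rules use mRNA Z and a pre-made copy-number call.
    Any satisfied condition makes the sample defective (OR logic).
    """
    if rules == "tcga":
        evidence, observed = _gather_evidence(
            record, thresholds, use_cn_log2=True, use_cn_call=False, use_protein=False
        )
    elif rules == "metabric":
        evidence, observed = _gather_evidence(
            record, thresholds, use_cn_log2=False, use_cn_call=True, use_protein=False
        )
    else:
        raise ValueError(f"unknown rules label {rules!r}; expected 'tcga' or 'metabric'")
    if not observed:
        return StatusCall(record.sample_id, UNCLASSIFIABLE)
    if evidence:
        return StatusCall(record.sample_id, DEFECTIVE, frozenset(evidence))
    return StatusCall(record.sample_id, NOT_ALTERED)


def classify_cell_line(
    record: OmicsRecord,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> StatusCall:
    """Classify a cell line; adds protein-low as usable evidence.

    Defective iff truncating mutation OR protein low OR mRNA Z below cut
    OR copy-number loss (from log2 ratio or a pre-made call).
    """
    evidence, observed = _gather_evidence(
        record, thresholds, use_cn_log2=True, use_cn_call=True, use_protein=True
    )
    if not observed:
        return StatusCall(record.sample_id, UNCLASSIFIABLE)
    if evidence:
        return StatusCall(record.sample_id, DEFECTIVE, frozenset(evidence))
    return StatusCall(record.sample_id, NOT_ALTERED)


def summarize_cohort(calls: Iterable[StatusCall]) -> tuple[int, int, int]:
    """Tally (n_defective, n_not_altered, n_unclassifiable)."""
    calls = list(calls)
    if not calls:
        raise ValueError("empty call list")
    n_def = sum(c.status == DEFECTIVE for c in calls)
    n_not = sum(c.status == NOT_ALTERED for c in calls)
    n_un = sum(c.status == UNCLASSIFIABLE for c in calls)
    return n_def, n_not, n_un


def classify_table(
    omics: pd.DataFrame,
    rules: str = "cellline",
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> list[StatusCall]:
    """Classify every row of an omics table (index = sample id).

    Recognised columns: mrna_z, cn_log2, cn_call, mutation, protein_low.
    ``rules`` is 'tcga', 'metabric' or 'cellline'.
    """

    def _get(row: pd.Series, col: str):
        if col not in omics.columns:
            return None
        v = row[col]
        if pd.isna(v):
            return None
        return v

    calls = []
    for sample_id, row in omics.iterrows():
        protein = _get(row, "protein_low")
        if protein is not None:
            protein = bool(protein) if not isinstance(protein, str) else protein == "True"
        record = OmicsRecord(
            sample_id=str(sample_id),
            mrna_z=_get(row, "mrna_z"),
            cn_log2=_get(row, "cn_log2"),
            cn_call=_get(row, "cn_call"),
            mutation=_get(row, "mutation"),
            protein_low=protein,
        )
        if rules == "cellline":
            calls.append(classify_cell_line(record, thresholds))
        else:
            calls.append(classify_tumour(record, rules, thresholds))
    return calls


def calls_to_frame(calls: Iterable[StatusCall]) -> pd.DataFrame:
    """Serialise calls as a table: sample_id, status, semicolon-joined evidence."""
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "status": [c.status for c in calls],
            "evidence": [";".join(sorted(c.evidence)) for c in calls],
        }
    )


def calls_from_frame(df: pd.DataFrame) -> list[StatusCall]:
    return [
        StatusCall(
            str(r.sample_id),
            r.status,
            frozenset(e for e in str(r.evidence).split(";") if e and e != "nan"),
        )
        for r in df.itertuples(index=False)
    ]
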