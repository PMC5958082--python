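"""miRNA-target direction consistency and qPCR cross-platform validation.

miRNAs predominantly destabilize their target transcripts, so a miRNA that
really drives a cluster should move opposite to the cluster in every
phenotype where the cluster moves.  Each enriched miRNA is classified as

* ``all_opposite`` — opposite to its cluster in ADU, ADT and ID;
* ``treated_opposite`` — opposite in the on-therapy phenotypes (ADT, ID)
  but not in ADU, i.e. consistent with a therapy-induced role;
* ``inconsistent`` — anything else.

qPCR fold changes use the comparative-Ct model: per sample the target Ct is
normalized by a reference assay (ΔCt = Ct_target − Ct_reference), group
means of ΔCt are differenced (ΔΔCt = ΔCt_case − ΔCt_control), and the fold
change is 2^−ΔΔCt.  Cross-platform concordance counts features whose array
log2 fold change and qPCR fold change agree in sign.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

QPCR_COLUMNS = ("sample_id", "phenotype", "feature_id",
                "ct_target", "ct_reference")


@dataclass(frozen=True)
class ConsistencyResult:
    """Directional agreement of one miRNA with its enriched cluster."""

    mirna_id: str
    cluster_id: str
    cluster_pattern: str
    mirna_log2fc: tuple[float, float, float]
    opposite_flags: tuple[bool, bool, bool]  # (ADU, ADT, ID)
    category: str


def direction_consistency(mirna_id: str,
                          mirna_log2fc_triple: Sequence[float],
                          cluster_pattern: str,
                          cluster_id: str | None = None
                          ) -> ConsistencyResult:
    """Classify a miRNA's direction triple against its cluster's pattern.

    Flag i is true iff the miRNA's fold-change sign in phenotype i is
    opposite to the cluster letter (cluster U needs a negative miRNA fold
    change, cluster D a positive one).  A zero miRNA fold change is never
    opposite (logged).  Attenuation case in the pattern's third letter is
    ignored for direction purposes.
    """
    if len(cluster_pattern) != 3:
        raise ValueError("cluster pattern must have 3 letters")
    letters = cluster_pattern.upper()
    if any(c not in "UD" for c in letters):
        raise ValueError(f"invalid cluster pattern {cluster_pattern!r}")
    fc = tuple(float(x) for x in mirna_log2fc_triple)
    if len(fc) != 3 or not all(math.isfinite(x) for x in fc):
        raise ValueError("need a finite log2fc triple over (ADU, ADT, ID)")
    flags = []
    for letter, x in zip(letters, fc):
        if x == 0:
            logger.warning("miRNA %s has log2fc 0 in one phenotype; "
                           "not counted as opposite", mirna_id)
            flags.append(False)
        else:
            flags.append(x < 0 if letter == "U" else x > 0)
    flags = tuple(flags)
    if all(flags):
        category = "all_opposite"
    elif flags[1] and flags[2]:
        category = "treated_opposite"
    else:
        category = "inconsistent"
    return ConsistencyResult(mirna_id=mirna_id,
                             cluster_id=cluster_id or cluster_pattern,
                             cluster_pattern=cluster_pattern,
                             mirna_log2fc=fc, opposite_flags=flags,
                             category=category)


# ---------------------------------------------------------------------------
# qPCR

def read_qpcr(path) -> pd.DataFrame:
    """Read a qPCR Ct table (TSV with the QPCR_COLUMNS header)."""
    df = pd.read_csv(path, sep="\t")
    validate_qpcr(df)
    return df


def write_qpcr(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def validate_qpcr(table: pd.DataFrame) -> None:
    missing = [c for c in QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    for col in ("ct_target", "ct_reference"):
        vals = pd.to_numeric(table[col], errors="coerce")
        ok = vals.notna() & (vals > 0) & (vals < float("inf"))
        if not ok.all():
            raise ValueError(f"qPCR column {col!r} must be finite and "
                             "positive")


def ddct_fold_change(qpcr: pd.DataFrame, case_phenotype: str,
                     control_phenotype: str = "HC"
                     ) -> dict[str, float]:
    """Per-feature 2^−ΔΔCt fold change between two phenotypes.

    ΔCt is computed per row (target minus reference), averaged within each
    phenotype group, and differenced case minus control.  Both phenotypes
    must contribute at least one sample per feature.
    """
    validate_qpcr(qpcr)
    out: dict[str, float] = {}
    for feature, sub in qpcr.groupby("feature_id"):
        dct = sub["ct_target"].astype(float) - \
            sub["ct_reference"].astype(float)
        case = dct[sub["phenotype"] == case_phenotype]
        ctrl = dct[sub["phenotype"] == control_phenotype]
        if case.empty or ctrl.empty:
            raise ValueError(
                f"feature {feature!r}: need both {case_phenotype} and "
                f"{control_phenotype} samples")
        ddct = case.mean() - ctrl.mean()
        out[str(feature)] = float(2.0 ** (-ddct))
    if not out:
        raise ValueError("empty qPCR table")
    return out


def platform_concordance(array_log2fc: Mapping[str, float],
                         qpcr_fold_change: Mapping[str, float]
                         ) -> tuple[int, int]:
    """Count features whose array and qPCR changes agree in sign.

    Concordant iff sign(array log2fc) == sign(log2 qPCR fold change); a
    fold change of exactly 1 (log2 = 0) is concordant only with a zero
    array fold change.  Returns (n_concordant, n_total) over the shared
    features.
    """
    shared = sorted(set(array_log2fc) & set(qpcr_fold_change))
    if not shared:
        raise ValueError("no shared features between platforms")
    n_conc = 0
    for f in shared:
        a = array_log2fc[f]
        q = math.log2(qpcr_fold_change[f])
        sign = lambda x: (x > 0) - (x < 0)
        if sign(a) == sign(q):
            n_conc += 1
    return n_conc, len(shared)
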