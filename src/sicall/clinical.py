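"""Closed-form clinical and assay rules.

Tumor/normal pair classification by regulator expression fold-change and
exon-inclusion shift, RIP-qPCR percent-input, and the ellipsoid
xenograft tumor-volume formula.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

logger = logging.getLogger(__name__)


@dataclass
class TumorPairRecord:
    """One matched tumor / non-tumor (NT) pair.

    ``adar1_fold`` / ``adar2_fold`` are tumor-over-NT expression ratios
    (qPCR-derived, > 0); PSIs are fractions in [0, 1].
    """

    patient_id: str
    adar1_fold: float
    adar2_fold: float
    psi_tumor: float
    psi_nt: float

    def __post_init__(self) -> None:
        if self.adar1_fold <= 0 or self.adar2_fold <= 0:
            raise ValueError("expression folds must be > 0")
        for psi in (self.psi_tumor, self.psi_nt):
            if not 0 <= psi <= 1:
                raise ValueError(f"PSI must be in [0, 1], got {psi}")


@dataclass
class PairClassification:
    patient_id: str
    adar12_group: str  # ADAR12_high | ADAR12_normal_low
    adar2_group: str  # ADAR2_high | ADAR2_normal_low
    inclusion_group: str  # up | down | no_change


def classify_pair(
    rec: TumorPairRecord,
    fold_threshold: float = 1.5,
    psi_threshold: float = 0.05,
) -> PairClassification:
    """Apply the expression and inclusion grouping rules.

    A pair is regulator-high when either fold is >= the threshold
    (inclusive); inclusion is up/down only when the PSI shift strictly
    exceeds the threshold (5 percentage points by default).
    """
    adar12 = (
        "ADAR12_high"
        if rec.adar1_fold >= fold_threshold or rec.adar2_fold >= fold_threshold
        else "ADAR12_normal_low"
    )
    adar2 = (
        "ADAR2_high" if rec.adar2_fold >= fold_threshold else "ADAR2_normal_low"
    )
    dpsi = rec.psi_tumor - rec.psi_nt
    eps = 1e-9  # strict inequality at the printed precision
    if dpsi > psi_threshold + eps:
        inclusion = "up"
    elif dpsi < -psi_threshold - eps:
        inclusion = "down"
    else:
        inclusion = "no_change"
    return PairClassification(rec.patient_id, adar12, adar2, inclusion)


def classify_pairs(
    records: Sequence[TumorPairRecord],
    fold_threshold: float = 1.5,
    psi_threshold: float = 0.05,
) -> list[PairClassification]:
    return [classify_pair(r, fold_threshold, psi_threshold) for r in records]


def rip_percent_input(
    ct_rip: float, ct_input: float, dilution_factor: float
) -> float:
    """RIP-qPCR enrichment as percent of input.

    %Input = 2^-dCt x 100 with dCt = Ct_RIP - (Ct_input -
    dilution_factor); the dilution factor is in Ct units (log2 of the
    input dilution).
    """
    dct = ct_rip - (ct_input - dilution_factor)
    return 2.0 ** (-dct) * 100.0


def tumor_volume(length: float, width: float) -> float:
    """Xenograft tumor volume, 0.5 x length x width^2 (mm^3).

    Length is the longer axis by convention; swapped inputs are
    corrected with a warning.
    """
    if length < 0 or width < 0:
        raise ValueError("dimensions must be non-negative")
    if width > length:
        logger.warning("width %.3g > length %.3g; swapping", width, length)
        length, width = width, length
    return 0.5 * length * width**2


def read_pairs_tsv(path: Union[str, Path]) -> list[TumorPairRecord]:
    """Read tumor pair records from a header TSV.

    Columns: patient_id, adar1_fold, adar2_fold, psi_tumor, psi_nt.
    Records with missing or invalid fields are skipped with a warning.
    """
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    TumorPairRecord(
                        patient_id=row["patient_id"],
                        adar1_fold=float(row["adar1_fold"]),
                        adar2_fold=float(row["adar2_fold"]),
                        psi_tumor=float(row["psi_tumor"]),
                        psi_nt=float(row["psi_nt"]),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                logger.warning("%s:%d: record skipped (%s)", path, lineno, exc)
    return out


def write_classifications(
    classes: Sequence[PairClassification], path: Union[str, Path]
) -> None:
    with open(path, "w") as fh:
        fh.write("patient_id\tadar12_group\tadar2_group\tinclusion_group\n")
        for c in classes:
            fh.write(
                f"{c.patient_id}\t{c.adar12_group}\t{c.adar2_group}"
                f"\t{c.inclusion_group}\n"
            )
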