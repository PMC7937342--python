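"""Efficiency-corrected Ct arithmetic and delta-Ct expression.

A qPCR amplicon with fractional efficiency E multiplies by (1+E) per cycle,
so a raw Ct is put on the perfect-doubling scale as

    corrected Ct = Ct * log2(1 + E)

(E = 1 is the identity). Relative expression of a target against the rpoB
reference is

    delta Ct = corrected Ct(reference) - corrected Ct(target),

which increases with target expression. A "literal" correction mode,
Ct * log2(E), is kept behind a flag for auditing alternative conventions;
it degenerates to 0 at E = 1 and is never the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

DEFAULT_RIP1_EFFICIENCY = 0.995  # measured amplification efficiency of the RIP1 primers


class QpcrDataError(ValueError):
    """Missing reference gene or malformed Ct table."""


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    gene: str
    ct: float
    efficiency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError(f"{self.sample_id}/{self.gene}: Ct must be positive")
        eff = self.resolved_efficiency
        if not 0 < eff <= 1.2:
            raise ValueError(
                f"{self.sample_id}/{self.gene}: efficiency {eff} outside (0, 1.2]"
            )

    @property
    def resolved_efficiency(self) -> float:
        if self.efficiency is not None:
            return self.efficiency
        if self.gene == "RIP1":
            return DEFAULT_RIP1_EFFICIENCY
        raise ValueError(f"{self.sample_id}/{self.gene}: efficiency not set")


@dataclass(frozen=True)
class DeltaCt:
    sample_id: str
    gene: str
    corrected_ct_gene: float
    corrected_ct_reference: float

    @property
    def delta(self) -> float:
        return self.corrected_ct_reference - self.corrected_ct_gene


def correct_ct(record: CtRecord, literal: bool = False) -> float:
    """Efficiency-corrected Ct: ct * log2(1 + E); E is fractional efficiency.

    ``literal=True`` computes ct * log2(E) instead (audit mode only).
    """
    eff = record.resolved_efficiency
    base = eff if literal else 1.0 + eff
    return record.ct * math.log2(base)


def delta_ct(
    records: Sequence[CtRecord],
    reference_gene: str = "rpoB",
    literal: bool = False,
) -> list[DeltaCt]:
    """Delta Ct per target gene of one sample: corrected reference minus
    corrected target. The reference gene must be present for the sample."""
    by_gene = {}
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) != 1:
        raise QpcrDataError(f"records span multiple samples: {sorted(sample_ids)}")
    sample_id = sample_ids.pop()
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    if reference_gene not in by_gene:
        raise QpcrDataError(f"sample {sample_id!r}: reference {reference_gene!r} missing")
    ref_corr = sum(correct_ct(r, literal) for r in by_gene[reference_gene]) / len(
        by_gene[reference_gene]
    )
    out = []
    for gene, recs in by_gene.items():
        if gene == reference_gene:
            continue
        for r in recs:
            out.append(
                DeltaCt(
                    sample_id=sample_id,
                    gene=gene,
                    corrected_ct_gene=correct_ct(r, literal),
                    corrected_ct_reference=ref_corr,
                )
            )
    return out


def delta_ct_table(
    frame: pd.DataFrame, reference_gene: str = "rpoB", literal: bool = False
) -> pd.DataFrame:
    """Tidy delta-Ct table from a (sample_id, gene, ct, efficiency) table.

    One output row per target measurement; any stats tool can consume it.
    """
    required = {"sample_id", "gene", "ct"}
    if not required.issubset(frame.columns):
        raise QpcrDataError(f"Ct table needs columns {sorted(required)}")
    rows = []
    for sample_id, sub in frame.groupby("sample_id", sort=True):
        records = [
            CtRecord(
                sample_id=str(sample_id),
                gene=str(r.gene),
                ct=float(r.ct),
                efficiency=(
                    float(r.efficiency)
                    if "efficiency" in frame.columns and pd.notna(r.efficiency)
                    else None
                ),
            )
            for r in sub.itertuples()
        ]
        for d in delta_ct(records, reference_gene, literal):
            rows.append({
                "sample_id": d.sample_id,
                "gene": d.gene,
                "corrected_ct_gene": d.corrected_ct_gene,
                "corrected_ct_reference": d.corrected_ct_reference,
                "delta_ct": d.delta,
            })
    return pd.DataFrame(rows)
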