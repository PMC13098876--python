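"""ΔΔCt relative quantification of qPCR gene expression.

Per-sample ΔCt = Ct(target) − Ct(reference gene); ΔΔCt = mean ΔCt of the
treated group minus mean ΔCt of the control group; fold change =
2^(−ΔΔCt).  Technical duplicates are averaged at the Ct level per sample
before ΔCt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["CtMeasurement", "FoldChange", "delta_delta_ct", "read_ct_table", "fold_change_table"]


@dataclass(frozen=True)
class CtMeasurement:
    """One well: target-gene Ct with its same-sample endogenous-control Ct."""

    sample: str
    group: str
    gene: str
    ct: float
    reference_ct: float

    def __post_init__(self):
        for name, v in (("ct", self.ct), ("reference_ct", self.reference_ct)):
            if v is None or not math.isfinite(v):
                raise ValueError(f"sample {self.sample}: {name} must be finite, got {v}")


@dataclass(frozen=True)
class FoldChange:
    gene: str
    group: str
    delta_delta_ct: float

    @property
    def fold(self) -> float:
        return 2.0 ** (-self.delta_delta_ct)


def _mean_delta_ct(measurements: list[CtMeasurement], gene: str) -> float:
    per_sample: dict[str, list[float]] = {}
    for m in measurements:
        if m.gene == gene:
            per_sample.setdefault(m.sample, []).append(m.ct - m.reference_ct)
    if not per_sample:
        raise ValueError(f"no measurements for gene {gene!r}")
    # technical duplicates averaged per sample, then samples averaged
    sample_means = [sum(v) / len(v) for v in per_sample.values()]
    return sum(sample_means) / len(sample_means)


def delta_delta_ct(
    treated: list[CtMeasurement], control: list[CtMeasurement], gene: str
) -> FoldChange:
    """Fold change of ``gene`` in the treated group relative to control."""
    d_treated = _mean_delta_ct(treated, gene)
    d_control = _mean_delta_ct(control, gene)
    group = treated[0].group if treated else "treated"
    return FoldChange(gene=gene, group=group, delta_delta_ct=d_treated - d_control)


def read_ct_table(path: str | Path) -> list[CtMeasurement]:
    """Read a Ct CSV with header sample,group,gene,ct,reference_ct."""
    df = pd.read_csv(path)
    missing = [c for c in ("sample", "group", "gene", "ct", "reference_ct") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = []
    for r in df.itertuples():
        out.append(
            CtMeasurement(str(r.sample), str(r.group), str(r.gene), float(r.ct), float(r.reference_ct))
        )
    return out


def fold_change_table(
    measurements: list[CtMeasurement], control_group: str
) -> pd.DataFrame:
    """Fold change of every (gene, non-control group) vs the pooled control."""
    control = [m for m in measurements if m.group == control_group]
    if not control:
        raise ValueError(f"no measurements in control group {control_group!r}")
    rows = []
    genes = sorted({m.gene for m in measurements})
    groups = sorted({m.group for m in measurements if m.group != control_group})
    for gene in genes:
        for group in groups:
            treated = [m for m in measurements if m.group == group and m.gene == gene]
            if not treated:
                continue
            fc = delta_delta_ct(treated, control, gene)
            rows.append(
                {"gene": gene, "group": group, "delta_delta_ct": fc.delta_delta_ct, "fold": fc.fold}
            )
    return pd.DataFrame(rows)
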