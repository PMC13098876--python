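"""End-to-end dose pipeline: biodistribution samples to per-organ doses.

Wires the stages together: aggregate replicates, build physical TACs,
integrate to cumulated activities, compute full-chain sphere S-values,
and multiply into Gy/MBq dose coefficients.  Used by the CLI and the
examples; every stage remains individually importable.
"""

from __future__ import annotations

import pandas as pd

from .biodist import BiodistSample, aggregate
from .dose import organ_dose_coefficient
from .nuclides import build_chain
from .svalue import SValueConfig, chain_s_value
from .tac import build_tac, cumulated_activity
from .nuclides import get_nuclide

__all__ = ["dose_report"]


def dose_report(
    samples: list[BiodistSample],
    nuclide: str,
    organ_masses_g: dict[str, float],
    svalue_config: SValueConfig = SValueConfig(),
    anchor_mode: str = "zero",
) -> pd.DataFrame:
    """Per-organ Ã, S and dose coefficient for every organ with a known mass.

    Returns a DataFrame with columns organ, mass_g, a_tilde_s,
    trapezoid_part_s, tail_part_s, s_mgy_per_mbq_s, dose_gy_per_mbq.
    Organs present in the samples but absent from ``organ_masses_g``
    raise, so silent omissions cannot occur.
    """
    parent = get_nuclide(nuclide)
    chain = build_chain(nuclide)
    series_by_organ = aggregate(samples)
    missing = sorted(set(series_by_organ) - set(organ_masses_g))
    if missing:
        raise KeyError(f"no organ mass supplied for: {missing}")
    rows = []
    for organ, series in series_by_organ.items():
        mass = organ_masses_g[organ]
        tac = build_tac(series, mass, parent, anchor_mode=anchor_mode)
        a_tilde = cumulated_activity(tac, parent)
        s = chain_s_value(chain, mass, svalue_config)
        dose = organ_dose_coefficient(a_tilde, s)
        rows.append(
            {
                "organ": organ,
                "mass_g": mass,
                "a_tilde_s": a_tilde.a_tilde_s,
                "trapezoid_part_s": a_tilde.trapezoid_part_s,
                "tail_part_s": a_tilde.tail_part_s,
                "s_mgy_per_mbq_s": s.s_mgy_per_mbq_s,
                "dose_gy_per_mbq": dose.dose_coefficient_gy_per_mbq,
            }
        )
    return pd.DataFrame(rows).sort_values("organ").reset_index(drop=True)
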