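"""Radioisotope bookkeeping for dual-label (45Ca + 14C) incubation vials.

Converts counted activities into moles incorporated via the specific
concentration of each label, applies the magnesium adjustment (high-Mg
calcite deposits Mg alongside Ca, which the 45Ca channel alone misses) and
the direct-deposition blank correction, and forms the organismal
CO2-released : carbonate-precipitated ratio psi_I.

Rates are cumulative by default: a vial sampled at time ``T`` yields
``absolute = rate * T``.  Per-interval rates between consecutive timepoints
are available from group means via :func:`interval_rates`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Tracer",
    "Treatment",
    "LabelSpec",
    "VialRecord",
    "IncorporationResult",
    "incorporation",
    "mg_adjust",
    "correct_direct_deposition",
    "psi_i",
    "process_table",
    "group_summary",
    "interval_rates",
    "psi_i_table",
    "psi_i_group",
    "mass_increase_percent_per_day",
    "read_vial_csv",
    "CSV_COLUMNS",
    "SEAWATER_CA_MOL_KG",
    "DEFAULT_DIC_MOL_KG",
    "DEFAULT_MG_OVER_CA",
]

#: Mean seawater calcium at S=35 (mol kg-1).
SEAWATER_CA_MOL_KG = 0.01028
#: Default vial DIC used for the 14C label pool (mol kg-1).
DEFAULT_DIC_MOL_KG = 0.0021
#: Default molar Mg/Ca of high-Mg calcite coralline skeleton.
DEFAULT_MG_OVER_CA = 0.15

TIMEPOINTS_H = (0.5, 1.5, 3.0, 5.0)


class UsageError(RuntimeError):
    """An operation was applied in an invalid order (e.g. twice)."""


class Tracer(str, Enum):
    ca45 = "ca45"
    c14_inorganic = "c14_inorganic"
    c14_organic = "c14_organic"
    c14_co2 = "c14_co2"


class Treatment(str, Enum):
    control = "control"
    ez = "EZ"


#: CSV schema shared by the synthetic generator (writer) and this module
#: (reader).  One row per vial; o2 column may be empty.
CSV_COLUMNS = [
    "vial_id",
    "treatment",
    "timepoint_h",
    "dry_mass_g",
    "act_ca45_skel_kbq",
    "act_c14_skel_kbq",
    "act_c14_org_kbq",
    "act_c14_co2_kbq",
    "o2_rate_umol_h_g",
]

_CHANNEL_COLUMN = {
    Tracer.ca45: "act_ca45_skel_kbq",
    Tracer.c14_inorganic: "act_c14_skel_kbq",
    Tracer.c14_organic: "act_c14_org_kbq",
    Tracer.c14_co2: "act_c14_co2_kbq",
}


@dataclass(frozen=True)
class LabelSpec:
    """A radiolabel added to a vial and the carrier pool it traces.

    ``specific_conc`` (nmol kBq-1) converts counted activity into moles of
    the traced species: the carrier pool divided by the activity added.
    """

    activity_added_kbq: float
    vial_volume_l: float
    carrier_pool_mol: float

    def __post_init__(self) -> None:
        if self.activity_added_kbq <= 0:
            raise ValueError("activity_added_kbq must be positive")
        if self.vial_volume_l <= 0:
            raise ValueError("vial_volume_l must be positive")
        if self.carrier_pool_mol <= 0:
            raise ValueError("carrier_pool_mol must be positive")

    @property
    def specific_conc(self) -> float:
        """nmol of carrier per kBq of label."""
        return self.carrier_pool_mol * 1e9 / self.activity_added_kbq

    @classmethod
    def ca45(
        cls,
        activity_kbq: float = 600.0,
        vial_volume_l: float = 0.02,
        ca_mol_kg: float = SEAWATER_CA_MOL_KG,
    ) -> "LabelSpec":
        """45CaCl2 label over the seawater Ca2+ pool (1 l taken as 1 kg)."""
        return cls(activity_kbq, vial_volume_l, ca_mol_kg * vial_volume_l)

    @classmethod
    def c14(
        cls,
        activity_kbq: float = 600.0,
        vial_volume_l: float = 0.02,
        dic_mol_kg: float = DEFAULT_DIC_MOL_KG,
    ) -> "LabelSpec":
        """NaH14CO3 label over the vial DIC pool."""
        return cls(activity_kbq, vial_volume_l, dic_mol_kg * vial_volume_l)


@dataclass(frozen=True)
class VialRecord:
    """One incubation vial: activities per channel, mass, time, treatment."""

    vial_id: str
    treatment: Treatment
    timepoint_h: float
    dry_mass_g: float
    act_ca45_skel_kbq: float
    act_c14_skel_kbq: float
    act_c14_org_kbq: float
    act_c14_co2_kbq: float
    o2_rate_umol_h_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dry_mass_g <= 0:
            raise ValueError(f"vial {self.vial_id}: dry_mass_g must be positive")
        if self.timepoint_h <= 0:
            raise ValueError(f"vial {self.vial_id}: timepoint_h must be positive")
        for ch in _CHANNEL_COLUMN.values():
            if getattr(self, ch) < 0:
                raise ValueError(f"vial {self.vial_id}: {ch} must be >= 0")

    def activity(self, tracer: Tracer) -> float:
        return getattr(self, _CHANNEL_COLUMN[tracer])


@dataclass(frozen=True)
class IncorporationResult:
    """Absolute (nmol g-1) and rate (nmol h-1 g-1) incorporation."""

    tracer: Tracer
    absolute: float
    rate: float
    mg_adjusted: bool = False
    corrected: bool = False


def incorporation(
    record: VialRecord, label_spec: LabelSpec, tracer: Tracer | str
) -> IncorporationResult:
    """Moles incorporated per gram from counted activity.

    rate = activity * specific_conc / (M * T); absolute = rate * T.
    """
    tracer = Tracer(tracer)
    rate = record.activity(tracer) * label_spec.specific_conc / (
        record.dry_mass_g * record.timepoint_h
    )
    return IncorporationResult(
        tracer=tracer, absolute=rate * record.timepoint_h, rate=rate
    )


def mg_adjust(
    ca_result: IncorporationResult, mg_over_ca: float = DEFAULT_MG_OVER_CA
) -> IncorporationResult:
    """Scale 45Ca incorporation up by (1 + Mg/Ca) to count co-precipitated Mg.

    Only meaningful on the 45Ca channel; applying it twice is a usage error.
    """
    if ca_result.tracer is not Tracer.ca45:
        raise UsageError("mg_adjust applies to the ca45 channel only")
    if ca_result.mg_adjusted:
        raise UsageError("mg_adjust already applied")
    if mg_over_ca < 0:
        raise ValueError("mg_over_ca must be >= 0")
    f = 1.0 + mg_over_ca
    return replace(
        ca_result, absolute=ca_result.absolute * f, rate=ca_result.rate * f,
        mg_adjusted=True,
    )


def correct_direct_deposition(
    result: IncorporationResult, blank_rate: float
) -> IncorporationResult:
    """Subtract a blank rate for passive label deposition on bare skeleton.

    The corrected rate is floored at zero; a clamp is logged, since a blank
    exceeding the measurement is informative about noise.
    """
    if blank_rate < 0:
        raise ValueError("blank_rate must be >= 0")
    corrected = result.rate - blank_rate
    if corrected < 0:
        logger.warning(
            "direct-deposition blank %.4g exceeds rate %.4g on %s; clamping to 0",
            blank_rate, result.rate, result.tracer.value,
        )
        corrected = 0.0
    # absolute = rate * T for cumulative results; T is not stored on the
    # result, so recover it to preserve the invariant after correction.
    duration = result.absolute / result.rate if result.rate > 0 else 0.0
    return replace(
        result, rate=corrected, absolute=corrected * duration, corrected=True
    )


def psi_i(
    co2_production: float, organic_fixation: float, ca_mg_incorporation: float
) -> float:
    """Organismal CO2-released : carbonate-precipitated ratio.

    psi_I = (14CO2 production - organic 14C fixation) / Mg-adjusted 45Ca
    incorporation, all three in the same units.  Negative values are
    reported with a warning, never clamped — at early timepoints they simply
    reflect counting noise.
    """
    if ca_mg_incorporation <= 0:
        raise ValueError("ca_mg_incorporation must be positive")
    value = (co2_production - organic_fixation) / ca_mg_incorporation
    if value < 0:
        warnings.warn(
            f"negative psi_I ({value:.4g}): CO2 production below organic fixation",
            stacklevel=2,
        )
    return value


def mass_increase_percent_per_day(
    rate_nmol_h_g: float, molar_mass_g_mol: float = 100.09
) -> float:
    """Convenience conversion of a Ca+Mg deposition rate to % dry mass day-1.

    Treats the deposit as CaCO3-equivalent (molar mass ~100 g mol-1):
    rate * 24 h * molar_mass * 1e-9 g nmol-1 * 100.  Note the result is of
    order 1e-3 % day-1 for rates around 1.5 nmol h-1 g-1 — three orders of
    magnitude below commonly quoted coralline growth figures — so this is a
    diagnostic, not a validated growth estimate.
    """
    return rate_nmol_h_g * 24.0 * molar_mass_g_mol * 1e-9 * 100.0


# ---------------------------------------------------------------------------
# Table-level pipeline
# ---------------------------------------------------------------------------


def read_vial_csv(path) -> pd.DataFrame:
    """Read the per-vial CSV (schema in :data:`CSV_COLUMNS`) with validation."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"vial CSV missing required columns: {missing}")
    if "o2_rate_umol_h_g" not in df.columns:
        df["o2_rate_umol_h_g"] = np.nan
    return df


def _records(df: pd.DataFrame) -> Iterable[VialRecord]:
    for row in df.itertuples(index=False):
        o2 = getattr(row, "o2_rate_umol_h_g", None)
        yield VialRecord(
            vial_id=str(row.vial_id),
            treatment=Treatment(row.treatment),
            timepoint_h=float(row.timepoint_h),
            dry_mass_g=float(row.dry_mass_g),
            act_ca45_skel_kbq=float(row.act_ca45_skel_kbq),
            act_c14_skel_kbq=float(row.act_c14_skel_kbq),
            act_c14_org_kbq=float(row.act_c14_org_kbq),
            act_c14_co2_kbq=float(row.act_c14_co2_kbq),
            o2_rate_umol_h_g=None if o2 is None or pd.isna(o2) else float(o2),
        )


def process_table(
    df: pd.DataFrame,
    ca_label: Optional[LabelSpec] = None,
    c14_label: Optional[LabelSpec] = None,
    mg_over_ca: float = DEFAULT_MG_OVER_CA,
    blank_rates: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-vial incorporation for every channel (long format).

    The 45Ca channel is Mg-adjusted; ``blank_rates`` maps
    (tracer value, timepoint) -> blank rate in nmol h-1 g-1 for the
    direct-deposition correction (default: no correction).

    Returns one row per vial x channel with columns vial_id, treatment,
    timepoint_h, tracer, absolute_nmol_g, rate_nmol_h_g, mg_adjusted,
    corrected.
    """
    ca_label = ca_label or LabelSpec.ca45()
    c14_label = c14_label or LabelSpec.c14()
    blank_rates = blank_rates or {}
    rows = []
    for rec in _records(df):
        for tracer in Tracer:
            label = ca_label if tracer is Tracer.ca45 else c14_label
            res = incorporation(rec, label, tracer)
            if tracer is Tracer.ca45:
                res = mg_adjust(res, mg_over_ca)
            blank = blank_rates.get((tracer.value, rec.timepoint_h))
            if blank is not None:
                res = correct_direct_deposition(res, blank)
            rows.append(
                {
                    "vial_id": rec.vial_id,
                    "treatment": rec.treatment.value,
                    "timepoint_h": rec.timepoint_h,
                    "tracer": tracer.value,
                    "absolute_nmol_g": res.absolute,
                    "rate_nmol_h_g": res.rate,
                    "mg_adjusted": res.mg_adjusted,
                    "corrected": res.corrected,
                }
            )
    return pd.DataFrame(rows)


def group_summary(per_vial: pd.DataFrame) -> pd.DataFrame:
    """Mean, sd (ddof=1) and n per treatment x timepoint x tracer."""
    g = per_vial.groupby(["treatment", "timepoint_h", "tracer"], sort=True)
    out = g.agg(
        mean_rate=("rate_nmol_h_g", "mean"),
        sd_rate=("rate_nmol_h_g", lambda s: s.std(ddof=1)),
        mean_absolute=("absolute_nmol_g", "mean"),
        sd_absolute=("absolute_nmol_g", lambda s: s.std(ddof=1)),
        n=("rate_nmol_h_g", "size"),
    ).reset_index()
    return out


def interval_rates(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-interval rates between consecutive timepoints from group means.

    (mean_absolute(t_i) - mean_absolute(t_{i-1})) / (t_i - t_{i-1}), with the
    first interval anchored at the origin.
    """
    rows = []
    for (treatment, tracer), g in summary.groupby(["treatment", "tracer"]):
        g = g.sort_values("timepoint_h")
        prev_t, prev_abs = 0.0, 0.0
        for row in g.itertuples(index=False):
            dt = row.timepoint_h - prev_t
            rows.append(
                {
                    "treatment": treatment,
                    "tracer": tracer,
                    "interval_start_h": prev_t,
                    "interval_end_h": row.timepoint_h,
                    "interval_rate_nmol_h_g": (row.mean_absolute - prev_abs) / dt,
                }
            )
            prev_t, prev_abs = row.timepoint_h, row.mean_absolute
    return pd.DataFrame(rows)


def psi_i_table(
    per_vial: pd.DataFrame, treatment: Treatment | str = Treatment.ez
) -> pd.DataFrame:
    """Per-vial psi_I within one treatment (the CA-inhibited group by default,
    which removes CCM-derived label from the numerator), plus nothing else —
    summarise with :func:`group_summary`-style aggregation downstream.

    Returns columns vial_id, treatment, timepoint_h, psi_i.
    """
    treatment = Treatment(treatment)
    sub = per_vial[per_vial["treatment"] == treatment.value]
    wide = sub.pivot_table(
        index=["vial_id", "timepoint_h"], columns="tracer",
        values="rate_nmol_h_g",
    ).reset_index()
    needed = {Tracer.c14_co2.value, Tracer.c14_organic.value, Tracer.ca45.value}
    if not needed <= set(wide.columns):
        raise ValueError(f"psi_i_table needs channels {sorted(needed)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # negatives summarised, not per-vial warned
        values = [
            psi_i(
                row[Tracer.c14_co2.value],
                row[Tracer.c14_organic.value],
                row[Tracer.ca45.value],
            )
            for _, row in wide.iterrows()
        ]
    out = wide[["vial_id", "timepoint_h"]].copy()
    out["treatment"] = treatment.value
    out["psi_i"] = values
    n_neg = int((out["psi_i"] < 0).sum())
    if n_neg:
        warnings.warn(f"{n_neg} vials with negative psi_I (noise at early timepoints)")
    return out[["vial_id", "treatment", "timepoint_h", "psi_i"]]


def psi_i_group(
    per_vial: pd.DataFrame, treatment: Treatment | str = Treatment.ez
) -> pd.DataFrame:
    """Cohort-level psi_I per timepoint as a ratio of group means.

    Averaging per-vial ratios (:func:`psi_i_table`) carries the usual ratio
    bias, ~cv^2 of the multiplicative measurement noise on the denominator;
    forming (mean CO2 production - mean organic fixation) / (mean Mg-adjusted
    Ca incorporation) instead keeps the estimator consistent for the true
    ratio.  Returns columns treatment, timepoint_h, psi_i, n.
    """
    treatment = Treatment(treatment)
    sub = per_vial[per_vial["treatment"] == treatment.value]
    rows = []
    for t, g in sub.groupby("timepoint_h"):
        means = g.groupby("tracer")["rate_nmol_h_g"].mean()
        n = g[g["tracer"] == Tracer.ca45.value].shape[0]
        rows.append(
            {
                "treatment": treatment.value,
                "timepoint_h": t,
                "psi_i": psi_i(
                    means[Tracer.c14_co2.value],
                    means[Tracer.c14_organic.value],
                    means[Tracer.ca45.value],
                ),
                "n": n,
            }
        )
    return pd.DataFrame(rows)
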