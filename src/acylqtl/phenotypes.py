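"""HPLC-derived anthocyanin traits from compound peak areas.

The compound catalogue follows the eight chromatogram peaks quantified at
520 nm in pigmented maize aleurone: cyanidin / pelargonidin / peonidin
3-glucosides and their malonylated derivatives.  Two peaks are co-elution
bundles treated as single compounds: the Pn3G bundle (non-acylated) and the
Pn3MG + C3DMG peak (acylated).  Peak "ID6" is an unidentified compound that
elutes with the acylated group and is counted as acylated.

Traits:

* acylation percentage -- 100 x (sum of acylated areas) / (total area);
* anthocyanin content (AC, mg/kg cyanidin-3-glucoside equivalents) -- external
  standard method: a reference extract of known AC = 1000 mg/kg maps total
  area to concentration proportionally;
* replicate CV -- 100 x sd / mean over replicate AC measurements;
* reduced-acylation classification -- acylation < 50%;
* kernel-marker scores for the R1 (speckling) and C1 (colorless) loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidStandardError

#: Compound ID -> acylated flag, in chromatogram order (Fig-style IDs 1-8).
COMPOUNDS: dict[str, bool] = {
    "C3G": False,          # ID 1, cyanidin 3-glucoside
    "Pg3G": False,         # ID 2, pelargonidin 3-glucoside
    "Pn3G": False,         # ID 3, peonidin 3-glucoside co-elution bundle
    "C3MG": True,          # ID 4, cyanidin 3-(6''-malonyl)glucoside
    "Pg3MG": True,         # ID 5, pelargonidin 3-(6''-malonyl)glucoside
    "ID6": True,           # ID 6, unidentified acylated peak
    "Pn3MG_C3DMG": True,   # ID 7, Pn3MG + C3DMG co-elution
    "Pg3DMG": True,        # ID 8, pelargonidin 3-(3'',6''-dimalonyl)glucoside
}

ACYLATED = tuple(c for c, a in COMPOUNDS.items() if a)
NON_ACYLATED = tuple(c for c, a in COMPOUNDS.items() if not a)

#: External standard: reference extract of known anthocyanin content.
STANDARD_AC_MG_KG = 1000.0


def acylation_percentage(areas: pd.Series | dict) -> float:
    """Percent of total peak area contributed by acylated compounds.

    Unknown compound columns are counted in the denominator only.  A zero
    total area is an undefined trait and returns NaN (the sample is excluded
    from acylation analyses downstream).
    """
    s = pd.Series(areas, dtype=float)
    if (s < 0).any():
        raise InvalidInputError("peak areas must be non-negative")
    total = s.sum()
    if total <= 0:
        return float("nan")
    acyl = s.reindex(ACYLATED).fillna(0.0).sum()
    return float(100.0 * acyl / total)


def anthocyanin_content(
    sample_total_area: float,
    standard_total_area: float,
    standard_ac: float = STANDARD_AC_MG_KG,
    mass_volume_scale: float = 1.0,
) -> float:
    """AC in mg/kg via the external-standard proportion.

    ``mass_volume_scale`` corrects for extraction-geometry differences between
    sample and standard; it defaults to 1 (identical geometry).
    """
    if standard_total_area <= 0:
        raise InvalidStandardError("standard total area must be positive")
    return float(standard_ac * (sample_total_area / standard_total_area) * mass_volume_scale)


def replicate_cv(values) -> float:
    """Coefficient of variation (%) of replicate AC measurements.

    Sample standard deviation (ddof=1) over the mean, times 100.  Undefined
    (NaN) when the mean is zero or non-positive.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InvalidInputError("replicate_cv needs at least two replicates")
    mean = v.mean()
    if mean <= 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / mean)


def classify_reduced_acylation(acylation_pct: float, cutoff: float = 50.0) -> bool:
    """Mutant iff acylation percentage is strictly below the cutoff (50%)."""
    return bool(acylation_pct < cutoff)


@dataclass(frozen=True)
class KernelObservation:
    """Visual kernel scores for one ear."""

    speckled: bool
    yellow_without_speckle: bool
    colorless_fraction: float


def score_marker_genes(
    obs: KernelObservation,
    colorless_band: tuple[float, float] = (0.4, 0.6),
) -> tuple[int, bool]:
    """Score the R1 and C1 marker genes from kernel observations.

    ``r1_score`` is 1 iff speckled kernels are present (R1 imprinting).
    ``c1_recessive`` is True iff the ear shows yellow kernels without
    speckling, or the colorless-kernel fraction falls inside the configurable
    band around 50% (default [0.4, 0.6]).
    """
    lo, hi = colorless_band
    r1_score = 1 if obs.speckled else 0
    c1_recessive = bool(
        obs.yellow_without_speckle or (lo <= obs.colorless_fraction <= hi)
    )
    return r1_score, c1_recessive


def derive_traits(
    peaks: pd.DataFrame,
    standard_total_area: float,
    standard_ac: float = STANDARD_AC_MG_KG,
    mass_volume_scale: float = 1.0,
    cutoff: float = 50.0,
) -> pd.DataFrame:
    """Per-sample derived traits from a replicate-level peak table.

    ``peaks`` has one row per sample-replicate with columns ``sample``,
    ``replicate``, and one column per compound.  Replicates are averaged
    before trait derivation; the CV is computed from the pre-averaged
    per-replicate AC values.
    """
    if "sample" not in peaks.columns:
        raise InvalidInputError("peak table needs a 'sample' column")
    compound_cols = [c for c in peaks.columns if c not in ("sample", "replicate")]
    rows = []
    for sample, grp in peaks.groupby("sample", sort=False):
        rep_totals = grp[compound_cols].sum(axis=1).to_numpy(dtype=float)
        rep_ac = np.array(
            [
                anthocyanin_content(t, standard_total_area, standard_ac, mass_volume_scale)
                for t in rep_totals
            ]
        )
        mean_areas = grp[compound_cols].mean(axis=0)
        ac = anthocyanin_content(
            float(mean_areas.sum()), standard_total_area, standard_ac, mass_volume_scale
        )
        acyl_pct = acylation_percentage(mean_areas)
        cv = replicate_cv(rep_ac) if len(rep_ac) >= 2 else float("nan")
        rows.append(
            {
                "sample": sample,
                "ac_mg_kg": ac,
                "acylation_pct": acyl_pct,
                "cv_pct": cv,
                "is_reduced_acylation": (
                    classify_reduced_acylation(acyl_pct, cutoff)
                    if np.isfinite(acyl_pct)
                    else False
                ),
                "undefined_trait": not np.isfinite(acyl_pct),
                **{c: float(mean_areas[c]) for c in compound_cols},
            }
        )
    return pd.DataFrame(rows)
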