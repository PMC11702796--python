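"""Consensus mutation-impact scoring on a common free-energy scale.

Every stability readout is first converted to kcal/mol:

* melting-point shifts (simulation or thermal denaturation)::

      ddG ≈ dH_m * dTm / Tm

  with dH_m the melting enthalpy (fitted van't Hoff enthalpy for the
  experiment, Cv-peak area for the simulation) and Tm the wild-type melting
  point used as the common reference;

* chemical denaturation::

      ddG ≈ m * dD1/2

  with m the denaturation slope and dD1/2 a midpoint-concentration shift;

* predictor tools supply ddG directly (sign convention
  ddG = dG_WT - dG_mut, negative = destabilising), reduced to one value per
  mutation by a configurable rule (default: mean across tools).

The four per-mutation components enter as absolute values — stabilising and
destabilising shifts both count as impact — and their sum is normalised by
the largest sum over mutations (the scaling factor), giving the
dimensionless Overall Impact in [0, 1] with exactly one mutation at 1.
Agreement with an external pathogenicity reference is summarised by the
Pearson correlation over the shared mutation set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .errors import ValidationError

COMPONENTS = ("ddg_pt", "ddg_rex", "ddg_td", "ddg_cd")


def ddg_from_tm_shift(dh_m: float, d_tm: float, tm: float) -> float:
    """ddG ≈ dH_m * dTm / Tm (kcal/mol); sign follows dTm."""
    if dh_m <= 0:
        raise ValidationError("melting enthalpy must be positive")
    if tm <= 0:
        raise ValidationError("melting temperature must be positive")
    return dh_m * d_tm / tm


def ddg_from_chemical(m_value: float, d_d: float) -> float:
    """ddG ≈ m * dD1/2 (kcal/mol); sign follows dD1/2."""
    if m_value <= 0:
        raise ValidationError("m-value must be positive")
    return m_value * d_d


def aggregate_predictor_ddg(table: pd.DataFrame,
                            rule: str = "mean") -> pd.Series:
    """Reduce per-(mutation, tool) ddG values to one signed value per mutation.

    ``rule`` is ``"mean"``, ``"median"``, or the name of a tool present for
    every mutation.
    """
    if len(table) == 0:
        raise ValidationError("empty predictor table")
    g = table.groupby("mutation")["ddg_kcal_mol"]
    if rule == "mean":
        return g.mean()
    if rule == "median":
        return g.median()
    sub = table[table["tool"] == rule]
    missing = set(table["mutation"]) - set(sub["mutation"])
    if missing:
        raise ValidationError(
            f"tool {rule!r} absent for mutations: {sorted(missing)}")
    return sub.set_index("mutation")["ddg_kcal_mol"]


@dataclass
class ImpactTable:
    """Per-mutation impact components and the normalised Overall Impact.

    ``table`` columns: the four signed components, their absolute values
    (``abs_*``), ``sum_abs`` and ``overall_impact``; ``scaling_factor`` is
    the largest ``sum_abs`` (kcal/mol); ``provenance`` records how each
    component was derived.
    """

    table: pd.DataFrame
    scaling_factor: float
    provenance: dict


def overall_impact(components: pd.DataFrame,
                   allow_missing: Iterable[str] = (),
                   provenance: Optional[Mapping] = None) -> ImpactTable:
    """Aggregate four signed ddG components into the normalised impact score.

    ``components`` is indexed by mutation with columns ddg_pt, ddg_rex,
    ddg_td, ddg_cd (kcal/mol).  NaN components are allowed only for
    mutations listed in ``allow_missing`` and contribute zero (recorded in
    provenance).
    """
    missing_cols = [c for c in COMPONENTS if c not in components.columns]
    if missing_cols:
        raise ValidationError(f"missing impact components: {missing_cols}")
    comp = components[list(COMPONENTS)].astype(float).copy()
    has_nan = comp.isna().any(axis=1)
    allowed = set(allow_missing)
    bad = [m for m in comp.index[has_nan] if m not in allowed]
    if bad:
        raise ValidationError(
            f"missing components for mutations {bad}; pass allow_missing to opt in")
    filled = comp.fillna(0.0)
    abs_comp = filled.abs()
    sums = abs_comp.sum(axis=1)
    scaling = float(sums.max())
    if scaling == 0.0:
        raise ValidationError("zero scaling factor: all components are zero")
    out = comp.copy()
    for c in COMPONENTS:
        out[f"abs_{c}"] = abs_comp[c]
    out["sum_abs"] = sums
    out["overall_impact"] = sums / scaling
    prov = dict(provenance or {})
    prov["missing_treated_as_zero"] = sorted(m for m in comp.index[has_nan])
    return ImpactTable(out, scaling, prov)


def correlate_with_reference(impacts: pd.Series,
                             reference: pd.Series) -> tuple[float, int]:
    """Pearson r between impact scores and reference scores (shared mutations).

    Returns ``(r, n_shared)``; requires at least 3 shared mutations and
    non-zero variance on both sides.
    """
    shared = impacts.index.intersection(reference.index)
    if len(shared) < 3:
        raise ValidationError(
            f"need at least 3 shared mutations, got {len(shared)}")
    a = impacts.loc[shared].to_numpy(float)
    b = reference.loc[shared].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("zero variance in impacts or reference scores")
    r = float(pearsonr(a, b).statistic)
    return r, int(len(shared))
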