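"""The 13C-labelling decision procedure for DNA-SIP taxon tables.

A taxon is called 13C labelled from its replicate-averaged relative abundance
in four fraction classes — 13C-heavy (a13H), 13C-light (a13L), 12C-heavy
(a12H), 12C-light (a12L) — when all of the following hold:

* abundance floor:  a13H > floor          (default 0.1 %)
* criterion 1:      a13H > a12H           (heavier than the 12C control)
* criterion 2:      a13H > k * a13L  and  a12H <= a12L

The factor k guards against cross-feeding (k = 10 for a substrate-based
methanol SIP, k = 2 for the more diffuse 13CO2 labelling).  Taxa also called
labelled in an unplanted control incubation (autotrophs fixing 13CO2) are
excluded from the test group's labelled list.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FractionProfile",
    "CallParameters",
    "LabelCall",
    "mean_profile",
    "call_taxon",
    "apply_control_exclusion",
    "call_experiment",
]

FRACTION_CLASSES = (("13C", "heavy"), ("13C", "light"), ("12C", "heavy"), ("12C", "light"))


@dataclass(frozen=True)
class FractionProfile:
    """A taxon's mean relative abundance in the four fraction classes."""

    taxon_id: str
    a13H: float
    a13L: float
    a12H: float
    a12L: float

    def __post_init__(self) -> None:
        for name in ("a13H", "a13L", "a12H", "a12L"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"{self.taxon_id}: {name}={v} is not a relative abundance in [0, 1]"
                )


@dataclass(frozen=True)
class CallParameters:
    """Decision thresholds: abundance floor and enrichment factor k.

    floor is a relative abundance (default 0.001, i.e. 0.1 %); k >= 1 is the
    heavy/light enrichment multiplier (10 for methanol SIP, 2 for CO2 SIP).
    """

    floor: float = 0.001
    k: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.floor < 1.0:
            raise ValueError(f"floor={self.floor} must lie in [0, 1)")
        if self.k < 1.0:
            raise ValueError(f"k={self.k} must be >= 1")


@dataclass(frozen=True)
class LabelCall:
    """Per-taxon decision record with every intermediate flag."""

    taxon_id: str
    passes_floor: bool
    criterion1: bool
    criterion2: bool
    labelled: bool
    final_status: str  # labelled | not_labelled | below_floor | excluded_control


def mean_profile(replicates: Sequence[FractionProfile]) -> FractionProfile:
    """Arithmetic mean of replicate profiles for one taxon.

    A taxon absent from a replicate must be supplied as an explicit zero
    profile by the caller building the list; this function averages exactly
    what it is given.
    """
    if not replicates:
        raise ValueError("cannot average an empty replicate list")
    ids = {p.taxon_id for p in replicates}
    if len(ids) != 1:
        raise ValueError(f"mixed taxon ids in replicate list: {sorted(ids)}")
    n = len(replicates)
    return FractionProfile(
        taxon_id=replicates[0].taxon_id,
        a13H=sum(p.a13H for p in replicates) / n,
        a13L=sum(p.a13L for p in replicates) / n,
        a12H=sum(p.a12H for p in replicates) / n,
        a12L=sum(p.a12L for p in replicates) / n,
    )


def call_taxon(profile: FractionProfile, params: CallParameters) -> LabelCall:
    """Apply the floor and the two labelling criteria to one profile.

    Strictness follows the stated rule exactly: the floor and both ">"
    comparisons are strict, the 12C control comparison a12H <= a12L is not.
    Note a13L = 0 with a13H > 0 passes the k test for any k.
    """
    passes_floor = profile.a13H > params.floor
    criterion1 = profile.a13H > profile.a12H
    criterion2 = (profile.a13H > params.k * profile.a13L) and (
        profile.a12H <= profile.a12L
    )
    labelled = passes_floor and criterion1 and criterion2
    if not passes_floor:
        status = "below_floor"
    elif labelled:
        status = "labelled"
    else:
        status = "not_labelled"
    return LabelCall(
        taxon_id=profile.taxon_id,
        passes_floor=passes_floor,
        criterion1=criterion1,
        criterion2=criterion2,
        labelled=labelled,
        final_status=status,
    )


def apply_control_exclusion(
    test_calls: Sequence[LabelCall], control_calls: Sequence[LabelCall]
) -> list[LabelCall]:
    """Remove taxa labelled in the control incubation from the test calls.

    Any taxon labelled in BOTH lists gets final_status 'excluded_control'
    (and labelled=False) in the returned test list; every other call is
    passed through unchanged, in input order.
    """
    control_labelled = {c.taxon_id for c in control_calls if c.final_status == "labelled"}
    out = []
    for call in test_calls:
        if call.final_status == "labelled" and call.taxon_id in control_labelled:
            out.append(replace(call, labelled=False, final_status="excluded_control"))
        else:
            out.append(call)
    return out


def _profiles_for_group(
    abundance: pd.DataFrame,
    samples: pd.DataFrame,
    treatment: str,
    timepoint: str,
) -> tuple[list[dict[str, FractionProfile]], list[str]]:
    """Per-replicate profiles for one (treatment, timepoint) group.

    Returns (per-replicate dict taxon -> profile, replicate labels).  Samples
    sharing (isotope, fraction_class, replicate) — e.g. several pooled heavy
    fractions — are averaged within the replicate.
    """
    grp = samples[(samples["treatment"] == treatment) & (samples["timepoint"] == timepoint)]
    for isotope, frac in FRACTION_CLASSES:
        if grp[(grp["isotope"] == isotope) & (grp["fraction_class"] == frac)].empty:
            raise ValueError(
                f"treatment {treatment!r} (timepoint {timepoint!r}) has no "
                f"{isotope}-{frac} fraction sample"
            )
    replicates = sorted(grp["replicate"].unique())
    per_rep: list[dict[str, FractionProfile]] = []
    for rep in replicates:
        rep_rows = grp[grp["replicate"] == rep]
        cls_means = {}
        for isotope, frac in FRACTION_CLASSES:
            ids = rep_rows[
                (rep_rows["isotope"] == isotope) & (rep_rows["fraction_class"] == frac)
            ]["sample_id"].tolist()
            if not ids:
                raise ValueError(
                    f"replicate {rep!r} of treatment {treatment!r} lacks a "
                    f"{isotope}-{frac} sample"
                )
            missing = [s for s in ids if s not in abundance.columns]
            if missing:
                raise ValueError(f"samples in sheet but not in table: {missing}")
            cls_means[(isotope, frac)] = abundance[ids].mean(axis=1)
        profiles = {
            taxon: FractionProfile(
                taxon_id=str(taxon),
                a13H=float(cls_means[("13C", "heavy")][taxon]),
                a13L=float(cls_means[("13C", "light")][taxon]),
                a12H=float(cls_means[("12C", "heavy")][taxon]),
                a12L=float(cls_means[("12C", "light")][taxon]),
            )
            for taxon in abundance.index
        }
        per_rep.append(profiles)
    return per_rep, [str(r) for r in replicates]


def _call_group(
    abundance: pd.DataFrame,
    samples: pd.DataFrame,
    treatment: str,
    timepoint: str,
    params: CallParameters,
    *,
    floor_per_replicate: bool,
    vote: bool,
) -> tuple[dict[str, LabelCall], dict[str, FractionProfile]]:
    per_rep, _ = _profiles_for_group(abundance, samples, treatment, timepoint)
    calls: dict[str, LabelCall] = {}
    mean_profiles: dict[str, FractionProfile] = {}
    for taxon in abundance.index:
        taxon = str(taxon)
        reps = [r[taxon] for r in per_rep]
        mean = mean_profile(reps)
        mean_profiles[taxon] = mean
        if vote:
            rep_calls = [call_taxon(p, params) for p in reps]
            n_lab = sum(c.labelled for c in rep_calls)
            labelled = n_lab * 2 > len(rep_calls)
            call = call_taxon(mean, params)
            if labelled != call.labelled:
                status = "labelled" if labelled else "not_labelled"
                call = replace(call, labelled=labelled, final_status=status)
        else:
            call = call_taxon(mean, params)
        if floor_per_replicate and not all(p.a13H > params.floor for p in reps):
            call = replace(call, passes_floor=False, labelled=False, final_status="below_floor")
        calls[taxon] = call
    return calls, mean_profiles


def call_experiment(
    abundance: pd.DataFrame,
    samples: pd.DataFrame,
    params: CallParameters,
    control_treatment: str | None = None,
    *,
    floor_per_replicate: bool = False,
    vote: bool = False,
) -> pd.DataFrame:
    """Run the full labelling procedure on an abundance table.

    Parameters
    ----------
    abundance
        taxa x samples relative-abundance matrix (rows sum to 1 per column).
    samples
        sample sheet with columns sample_id, treatment, isotope (13C/12C),
        fraction_class (heavy/light), replicate and optionally timepoint
        (defaults to a single timepoint "T1").
    params
        floor and k.
    control_treatment
        if given, taxa labelled in this treatment are set to
        'excluded_control' in every other treatment (per timepoint).
    floor_per_replicate
        apply the abundance floor to each replicate rather than to the
        replicate mean (off by default).
    vote
        call each replicate separately and label by majority vote instead of
        averaging first (off by default).

    Returns a tidy frame with one row per (taxon, treatment, timepoint) and
    all intermediate flags.
    """
    samples = samples.copy()
    if "timepoint" not in samples.columns:
        samples["timepoint"] = "T1"
    required = {"sample_id", "treatment", "isotope", "fraction_class", "replicate"}
    missing_cols = required - set(samples.columns)
    if missing_cols:
        raise ValueError(f"sample sheet missing columns: {sorted(missing_cols)}")
    unknown = set(abundance.columns) - set(samples["sample_id"])
    if unknown:
        raise ValueError(f"abundance table contains samples not in sheet: {sorted(unknown)}")

    rows = []
    for timepoint in sorted(samples["timepoint"].unique()):
        tp_sheet = samples[samples["timepoint"] == timepoint]
        treatments = sorted(tp_sheet["treatment"].unique())
        group_calls: dict[str, dict[str, LabelCall]] = {}
        group_profiles: dict[str, dict[str, FractionProfile]] = {}
        for treatment in treatments:
            calls, profiles = _call_group(
                abundance,
                samples,
                treatment,
                timepoint,
                params,
                floor_per_replicate=floor_per_replicate,
                vote=vote,
            )
            group_calls[treatment] = calls
            group_profiles[treatment] = profiles
        if control_treatment is not None:
            if control_treatment not in group_calls:
                raise ValueError(
                    f"control treatment {control_treatment!r} not present at "
                    f"timepoint {timepoint!r}"
                )
            control = list(group_calls[control_treatment].values())
            for treatment in treatments:
                if treatment == control_treatment:
                    continue
                excluded = apply_control_exclusion(
                    list(group_calls[treatment].values()), control
                )
                group_calls[treatment] = {c.taxon_id: c for c in excluded}
        for treatment in treatments:
            for taxon, call in group_calls[treatment].items():
                p = group_profiles[treatment][taxon]
                rows.append(
                    {
                        "taxon_id": taxon,
                        "treatment": treatment,
                        "timepoint": timepoint,
                        "a13H": p.a13H,
                        "a13L": p.a13L,
                        "a12H": p.a12H,
                        "a12L": p.a12L,
                        "passes_floor": call.passes_floor,
                        "criterion1": call.criterion1,
                        "criterion2": call.criterion2,
                        "final_status": call.final_status,
                    }
                )
    return pd.DataFrame(rows)
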