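"""Chromatic response computation and cross-plate normalization.

The percentage fluorescent chromatic response of a well is

    %FCR = 100 * (Em_i - Em_c) / (Em_r - Em_c)

where ``Em_i`` is the fluorescence after incubation with the tested serum,
``Em_c`` the background fluorescence of unexposed blue-phase vesicles
(estimated from the plate's negative color controls) and ``Em_r`` the
maximal fluorescence of fully converted red-phase vesicles (positive color
controls).  Because %FCR is a ratio of differences of same-plate readings,
it is exactly invariant under any common affine distortion (detector gain
and offset) applied to all wells of a plate.

Two further corrections align plates into one feature space:

1. **Standardization** — each plate carries identical aliquots of five
   standardization sera.  For each vesicle, the per-standard mean %FCR over
   all plates of that vesicle defines a reference profile; each plate is
   mapped onto the references by a least-squares affine fit (offset and
   scale) of its own five standard responses.  This removes residual
   plate-scale artifacts that survive the %FCR ratio (e.g. drift of the
   latent standard responses is not modeled; only affine scale/offset).
2. **Normalization** — per plate, the mean %FCR of the healthy-control-group
   serum samples on that plate is subtracted from every sample's %FCR and
   the result divided by the standard deviation (sample SD, n-1) of those
   control samples.  Control samples on each plate therefore have mean 0 and
   SD 1 by construction, and the resulting values are dimensionless
   features, one per detector vesicle.

%FCR is never clipped to [0, 100]: under noise the ratio can exceed either
bound and clipping would bias downstream statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .plate_model import Plate, ReactomicsError

logger = logging.getLogger("reactomics")


class DegeneratePlateError(ReactomicsError):
    """A plate's red-phase control does not exceed its blue background."""


class NormalizationError(ReactomicsError):
    """Per-plate control normalization is undefined (too few controls, zero SD)."""


@dataclass
class FcrTable:
    """Per-plate %FCR values after replicate aggregation.

    ``data`` has one row per serum on the plate (clinical samples and
    standardization sera) with columns ``sample_id, role, group, fcr``.
    ``em_c`` / ``em_r`` are the control-based estimates used to compute the
    ratios.
    """

    plate_id: str
    vesicle_id: str
    em_c: float
    em_r: float
    data: pd.DataFrame

    def copy(self) -> "FcrTable":
        return FcrTable(self.plate_id, self.vesicle_id, self.em_c, self.em_r,
                        self.data.copy())


@dataclass
class FeatureMatrix:
    """Samples x vesicles matrix of standardized, normalized %FCR features.

    ``values`` is indexed by sample_id with one column per detector vesicle;
    ``groups`` maps each sample_id to its clinical group.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            raise ReactomicsError("FeatureMatrix values and groups indices differ")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def subset_groups(self, groups: tuple[str, ...]) -> "FeatureMatrix":
        mask = self.groups.isin(groups)
        return FeatureMatrix(self.values.loc[mask], self.groups.loc[mask])

    def __len__(self) -> int:
        return len(self.values)


def compute_fcr(em_i, em_c: float, em_r: float):
    """Percentage fluorescent chromatic response of a reading.

    Accepts a scalar or array ``em_i``; raises
    :class:`DegeneratePlateError` when the red-phase maximum does not exceed
    the blue background (the ratio is then meaningless).
    """
    if em_r <= em_c:
        raise DegeneratePlateError(
            f"Em_r ({em_r!r}) must exceed Em_c ({em_c!r})"
        )
    return (np.asarray(em_i, dtype=float) - em_c) / (em_r - em_c) * 100.0


def aggregate_plate(plate: Plate) -> FcrTable:
    """Compute per-serum %FCR for one plate.

    ``Em_c`` / ``Em_r`` are the means of the plate's negative / positive
    color-control wells; each serum's %FCR is the mean over its replicate
    wells.  Standardization sera are aggregated alongside clinical samples
    (they are needed for cross-plate standardization) and keep their role.
    """
    emissions = np.array([w.emission for w in plate.wells])
    roles = np.array([w.role for w in plate.wells])
    em_c = float(emissions[roles == "neg_control"].mean())
    em_r = float(emissions[roles == "pos_control"].mean())
    if em_r <= em_c:
        raise DegeneratePlateError(
            f"plate {plate.plate_id!r}: mean positive control ({em_r:.3f}) does not "
            f"exceed mean negative control ({em_c:.3f})"
        )
    rows = []
    for w in plate.wells:
        if w.role in ("sample", "standard"):
            rows.append((w.sample_id, w.role, w.group, w.emission))
    frame = pd.DataFrame(rows, columns=["sample_id", "role", "group", "emission"])
    agg = (
        frame.groupby("sample_id", sort=False)
        .agg(role=("role", "first"), group=("group", "first"),
             emission=("emission", "mean"))
        .reset_index()
    )
    agg["fcr"] = compute_fcr(agg.pop("emission").to_numpy(), em_c, em_r)
    return FcrTable(plate.plate_id, plate.vesicle_id, em_c, em_r, agg)


def _standards(table: FcrTable) -> pd.Series:
    stds = table.data[table.data["role"] == "standard"]
    return stds.set_index("sample_id")["fcr"].sort_index()


def standardize_across_plates(tables: list[FcrTable]) -> list[FcrTable]:
    """Align plates of each vesicle via their shared standardization sera.

    For every vesicle measured on two or more plates, the per-standard mean
    %FCR across those plates defines reference values.  Each plate's %FCRs
    are then mapped by ``x -> a + b*x`` with ``(a, b)`` the least-squares fit
    of the plate's own standard %FCRs to the references.  A plate whose
    standards have (near-)zero variance falls back to an offset-only
    correction with a logged warning.  Vesicles with a single plate pass
    through unchanged.  Input tables are not mutated; output order matches
    input order.
    """
    by_vesicle: dict[str, list[int]] = {}
    for i, t in enumerate(tables):
        by_vesicle.setdefault(t.vesicle_id, []).append(i)

    out: list[FcrTable] = [t.copy() for t in tables]
    for vesicle_id, idxs in by_vesicle.items():
        if len(idxs) < 2:
            continue
        std_profiles = [_standards(out[i]) for i in idxs]
        ids = std_profiles[0].index
        for i, prof in zip(idxs, std_profiles):
            if len(prof) == 0 or not prof.index.equals(ids):
                raise ReactomicsError(
                    f"plate {out[i].plate_id!r}: standardization sera missing or "
                    f"inconsistent; cannot standardize vesicle {vesicle_id!r}"
                )
        refs = pd.concat(std_profiles, axis=1).mean(axis=1)
        r = refs.to_numpy()
        for i, prof in zip(idxs, std_profiles):
            x = prof.to_numpy()
            sxx = float(np.sum((x - x.mean()) ** 2))
            if sxx < 1e-12:
                b = 1.0
                a = float(r.mean() - x.mean())
                logger.warning(
                    "plate %r: standards have zero variance; offset-only correction",
                    out[i].plate_id,
                )
            else:
                b = float(np.sum((x - x.mean()) * (r - r.mean())) / sxx)
                a = float(r.mean() - b * x.mean())
            out[i].data["fcr"] = a + b * out[i].data["fcr"].to_numpy()
    return out


def normalize_to_controls(
    tables: list[FcrTable], control_group: str = "control"
) -> FeatureMatrix:
    """Z-normalize each plate against its own control-group samples.

    Per plate: ``z = (x - mean_ctrl) / sd_ctrl`` with the mean and sample SD
    (n-1) taken over that plate's clinical samples belonging to
    ``control_group``; the transform is applied to all clinical samples of
    the plate.  Plate fragments are then assembled into a
    :class:`FeatureMatrix`; samples lacking a measurement for any vesicle
    are dropped with a logged warning.
    """
    entries = []
    vesicle_order: list[str] = []
    for t in tables:
        if t.vesicle_id not in vesicle_order:
            vesicle_order.append(t.vesicle_id)
        samples = t.data[t.data["role"] == "sample"]
        ctrl = samples.loc[samples["group"] == control_group, "fcr"]
        if len(ctrl) < 2:
            raise NormalizationError(
                f"plate {t.plate_id!r}: needs >=2 {control_group!r}-group samples "
                f"for normalization (found {len(ctrl)})"
            )
        sd = float(ctrl.std(ddof=1))
        if sd == 0.0:
            raise NormalizationError(
                f"plate {t.plate_id!r}: control-group SD is zero; "
                "normalization undefined"
            )
        mean = float(ctrl.mean())
        z = (samples["fcr"].to_numpy() - mean) / sd
        for sid, grp, val in zip(samples["sample_id"], samples["group"], z):
            entries.append((sid, grp, t.vesicle_id, val))

    frame = pd.DataFrame(entries, columns=["sample_id", "group", "vesicle_id", "z"])
    if frame.duplicated(["sample_id", "vesicle_id"]).any():
        raise ReactomicsError("a sample was measured twice for the same vesicle")
    values = frame.pivot(index="sample_id", columns="vesicle_id", values="z")
    values = values.reindex(columns=vesicle_order)
    groups = frame.drop_duplicates("sample_id").set_index("sample_id")["group"]
    incomplete = values.index[values.isna().any(axis=1)]
    for sid in incomplete:
        logger.warning("sample %r lacks measurements for some vesicles; dropped", sid)
    values = values.drop(index=incomplete)
    groups = groups.loc[values.index]
    values.columns.name = None
    groups.name = "group"
    return FeatureMatrix(values=values, groups=groups)


def compute_rsd(repeats) -> tuple[pd.Series, float]:
    """Relative standard deviation of repeated %FCR measurements per serum.

    ``repeats`` is either a DataFrame with columns ``sample_id`` and ``fcr``
    (several rows per serum) or a list of :class:`FcrTable` fragments whose
    clinical samples are pooled.  Returns ``(per_serum_rsd, average_rsd)``
    in percent: RSD = 100 * SD(repeats) / mean(repeats), sample SD (n-1).
    """
    if isinstance(repeats, list):
        frames = [t.data[t.data["role"] == "sample"] for t in repeats]
        frame = pd.concat(frames, ignore_index=True)
    else:
        frame = repeats
    grouped = frame.groupby("sample_id")["fcr"]
    counts = grouped.count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ReactomicsError(f"sera {bad} have fewer than 2 repeats")
    means = grouped.mean()
    if (means == 0).any():
        bad = means[means == 0].index.tolist()
        raise ReactomicsError(f"RSD undefined for sera with zero mean %FCR: {bad}")
    rsd = 100.0 * grouped.std(ddof=1) / means
    rsd.name = "rsd"
    return rsd, float(rsd.mean())
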