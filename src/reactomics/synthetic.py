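"""Synthetic plate cohorts with the statistical structure of a serum assay.

The generator emulates a three-group clinical cohort (healthy controls,
stomach cancer, pancreatic cancer; 50 sera each by default) measured in
triplicate against a ten-vesicle lipid/PDA panel.  Each serum ``s`` has a
latent true chromatic response ``f(s, v)`` per vesicle ``v``, drawn around a
group-by-vesicle mean on the 0-100 %FCR scale.  A well's raw emission is the
latent response mapped onto the plate's blue-to-red fluorescence span and
corrupted by replicate noise, then distorted by a per-plate affine artifact
(gain and offset) that the downstream standardization step is designed to
remove:

    emission = gain * (Em_c + f/100 * (Em_r - Em_c) + eps) + offset,
    eps ~ Normal(0, replicate_sd * (Em_r - Em_c) / 100)

Negative color controls receive the distorted blue background ``Em_c``
(f = 0), positive controls the distorted red-phase maximum ``Em_r``
(f = 100).  Five standardization sera with latent responses held fixed
across all plates of a vesicle are placed on every plate, mirroring the
assay design that makes cross-plate standardization possible.

One plate cannot hold 150 sera in triplicate plus controls and standards,
so sera are dealt across several plates per vesicle (25 samples per plate
with the default layout: 3+3 color controls, 5 standards x3, 25 samples x3
= 96 wells), each plate carrying its own controls and the full standard set.
Sera are assigned to plates by a seeded within-group shuffle followed by
round-robin dealing, so every plate holds a near-balanced mix of clinical
groups and, in particular, enough control-group sera for the per-plate
normalization step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .plate_model import (
    PanelSpec,
    Plate,
    ReactomicsError,
    WellMeasurement,
    default_panel,
)

logger = logging.getLogger("reactomics")


class ConfigError(ReactomicsError):
    """A synthetic-cohort configuration violates its invariants."""


_WELL_NAMES = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    ``group_effect`` is a groups x vesicles table of mean latent %FCR on the
    0-100 scale.  ``serum_sd`` is the between-serum SD of latent reactivity
    (in %FCR units), ``replicate_sd`` the within-triplicate noise SD (in %FCR
    units, i.e. as a fraction of the plate's blue-to-red span).  ``em_*``
    parameters set the per-plate blue background and red-phase maximum in
    arbitrary fluorescence units; ``plate_gain_sd`` / ``plate_offset_sd``
    scale the per-plate affine distortion.
    """

    panel: PanelSpec
    group_effect: pd.DataFrame  # index: groups, columns: vesicle ids, %FCR means
    groups: tuple[str, ...] = ("control", "stomach", "pancreas")
    n_per_group: int = 50
    em_c_mean: float = 30.0
    em_c_sd: float = 2.0
    em_r_mean: float = 150.0
    em_r_sd: float = 5.0
    serum_sd: float = 10.0
    replicate_sd: float = 4.0
    plate_gain_sd: float = 0.05
    plate_offset_sd: float = 2.0
    n_standards: int = 5
    standard_mean: float = 50.0
    replicate_count: int = 3
    n_neg_controls: int = 3
    n_pos_controls: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.em_r_mean <= self.em_c_mean:
            raise ConfigError(
                f"em_r_mean ({self.em_r_mean}) must exceed em_c_mean ({self.em_c_mean})"
            )
        for name in (
            "em_c_sd", "em_r_sd", "serum_sd", "replicate_sd",
            "plate_gain_sd", "plate_offset_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_per_group < 1 or self.n_standards < 0 or self.replicate_count < 1:
            raise ConfigError("cohort sizes must be positive")
        missing = [g for g in self.groups if g not in self.group_effect.index]
        if missing:
            raise ConfigError(f"groups {missing} absent from group_effect table")
        missing_v = [v for v in self.panel.ids if v not in self.group_effect.columns]
        if missing_v:
            raise ConfigError(f"vesicles {missing_v} absent from group_effect table")
        effects = self.group_effect.loc[list(self.groups), self.panel.ids].to_numpy()
        if np.any(effects < 0) or np.any(effects > 100):
            raise ConfigError("group_effect means must lie in [0, 100]")

    @property
    def samples_per_plate(self) -> int:
        overhead = (
            self.n_neg_controls
            + self.n_pos_controls
            + self.n_standards * self.replicate_count
        )
        cap = (96 - overhead) // self.replicate_count
        if cap < 1:
            raise ConfigError("plate layout leaves no room for samples")
        return cap


def default_study_config(seed: int = 0) -> SyntheticConfig:
    """Default three-group, ten-vesicle study configuration.

    Group-by-vesicle mean latent responses encode the qualitative clinical
    pattern: stomach-cancer sera react less than control sera on every
    vesicle, while pancreatic-cancer sera show a mixed response — elevated on
    the two cholesterol/PS-containing compositions v3 (DMPC/Chl/PDA 1:1:3)
    and v5 (DMPE/PS/PDA 1:1:3), and at-or-below control elsewhere.  Effect
    sizes were fixed once so that the default cohort supports
    pancreas-vs-control test accuracy in the 80-95% band.
    """
    panel = default_panel()
    ids = panel.ids
    control = {v: 50.0 for v in ids}
    stomach = {v: 45.0 for v in ids}
    pancreas = {v: 62.0 if v in ("v3", "v5") else 42.0 for v in ids}
    effect = pd.DataFrame(
        [control, stomach, pancreas], index=["control", "stomach", "pancreas"]
    )[ids]
    cfg = SyntheticConfig(panel=panel, group_effect=effect, seed=seed)
    cfg.validate()
    return cfg


def _latent_responses(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw latent %FCR per (serum, vesicle), truncated to [0, 100]."""
    rows = []
    index = []
    for group in cfg.groups:
        means = cfg.group_effect.loc[group, cfg.panel.ids].to_numpy(dtype=float)
        for i in range(cfg.n_per_group):
            sid = f"{group}-{i + 1:03d}"
            f = rng.normal(means, cfg.serum_sd)
            rows.append(np.clip(f, 0.0, 100.0))
            index.append((sid, group))
    for j in range(cfg.n_standards):
        f = rng.normal(np.full(len(cfg.panel), cfg.standard_mean), cfg.serum_sd)
        rows.append(np.clip(f, 0.0, 100.0))
        index.append((f"std-{j + 1}", "none"))
    frame = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["sample_id", "group"]),
        columns=cfg.panel.ids,
    )
    return frame


def _deal_to_plates(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> list[list[str]]:
    """Assign sample sera to plates: within-group shuffle, then round-robin."""
    n_total = cfg.n_per_group * len(cfg.groups)
    n_plates = -(-n_total // cfg.samples_per_plate)  # ceil
    order: list[str] = []
    shuffled = []
    for group in cfg.groups:
        ids = [f"{group}-{i + 1:03d}" for i in range(cfg.n_per_group)]
        shuffled.append([ids[k] for k in rng.permutation(len(ids))])
    # interleave groups so each plate receives a balanced mix
    for i in range(cfg.n_per_group):
        for g in range(len(cfg.groups)):
            order.append(shuffled[g][i])
    # chunk the interleaved order so each plate gets a near-equal group mix
    cap = cfg.samples_per_plate
    plates: list[list[str]] = [[] for _ in range(n_plates)]
    for i, sid in enumerate(order):
        plates[i // cap].append(sid)
    return plates


def generate_cohort(cfg: SyntheticConfig) -> list[Plate]:
    """Generate a full synthetic cohort, one or more plates per vesicle.

    Fully reproducible from ``cfg.seed``.  Returns validated plates.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    latents = _latent_responses(cfg, rng)
    group_of = {sid: g for sid, g in latents.index}
    assignments = _deal_to_plates(cfg, rng)
    standard_ids = [f"std-{j + 1}" for j in range(cfg.n_standards)]

    plates: list[Plate] = []
    for vesicle_id in cfg.panel.ids:
        for p_idx, sample_ids in enumerate(assignments):
            plate_id = f"{vesicle_id}-p{p_idx + 1}"
            em_c = rng.normal(cfg.em_c_mean, cfg.em_c_sd)
            em_r = rng.normal(cfg.em_r_mean, cfg.em_r_sd)
            if em_r <= em_c:
                raise ConfigError(
                    f"drawn plate span degenerate (Em_r {em_r:.2f} <= Em_c {em_c:.2f}); "
                    "reduce em_c_sd/em_r_sd or separate the means"
                )
            gain = rng.normal(1.0, cfg.plate_gain_sd)
            offset = rng.normal(0.0, cfg.plate_offset_sd)
            span = em_r - em_c
            noise_sd = cfg.replicate_sd * span / 100.0

            wells: list[WellMeasurement] = []
            cursor = 0

            def add_well(sample_id: str, role: str, group: str, f: float) -> None:
                nonlocal cursor
                eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                true = em_c + f / 100.0 * span + eps
                emission = gain * true + offset
                wells.append(
                    WellMeasurement(
                        plate_id=plate_id,
                        vesicle_id=vesicle_id,
                        well=_WELL_NAMES[cursor],
                        sample_id=sample_id,
                        role=role,
                        group=group,
                        emission=max(emission, 0.0),
                    )
                )
                cursor += 1

            for _ in range(cfg.n_neg_controls):
                add_well("", "neg_control", "none", 0.0)
            for _ in range(cfg.n_pos_controls):
                add_well("", "pos_control", "none", 100.0)
            for sid in standard_ids:
                f = latents.loc[(sid, "none"), vesicle_id]
                for _ in range(cfg.replicate_count):
                    add_well(sid, "standard", "none", f)
            for sid in sample_ids:
                g = group_of[sid]
                f = latents.loc[(sid, g), vesicle_id]
                for _ in range(cfg.replicate_count):
                    add_well(sid, "sample", g, f)

            plate = Plate(
                plate_id=plate_id,
                vesicle_id=vesicle_id,
                wells=wells,
                replicate_count=cfg.replicate_count,
            )
            plate.validate(standard_ids=set(standard_ids) or None)
            plates.append(plate)
    return plates


def generate_repeat_assay(
    cfg: SyntheticConfig,
    vesicle_id: str | None = None,
    n_sera: int = 5,
    n_repeats: int = 10,
) -> list[Plate]:
    """Generate a repeatability assay: the same sera measured on many plates.

    ``n_sera`` control-group sera with latent responses held fixed are run in
    triplicate on ``n_repeats`` plates of a single vesicle, mimicking a
    repeat-assay used to estimate the relative standard deviation (RSD) of
    the chromatic response.
    """
    cfg.validate()
    vesicle_id = vesicle_id or cfg.panel.ids[0]
    rng = np.random.default_rng(cfg.seed)
    mean = float(cfg.group_effect.loc[cfg.groups[0], vesicle_id])
    latents = np.clip(rng.normal(mean, cfg.serum_sd, size=n_sera), 0.0, 100.0)
    sera = [f"rep-{i + 1}" for i in range(n_sera)]

    plates: list[Plate] = []
    for r in range(n_repeats):
        plate_id = f"{vesicle_id}-rep{r + 1}"
        em_c = rng.normal(cfg.em_c_mean, cfg.em_c_sd)
        em_r = rng.normal(cfg.em_r_mean, cfg.em_r_sd)
        gain = rng.normal(1.0, cfg.plate_gain_sd)
        offset = rng.normal(0.0, cfg.plate_offset_sd)
        span = em_r - em_c
        noise_sd = cfg.replicate_sd * span / 100.0
        wells = []
        cursor = 0

        def add_well(sample_id: str, role: str, group: str, f: float) -> None:
            nonlocal cursor
            eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            emission = gain * (em_c + f / 100.0 * span + eps) + offset
            wells.append(
                WellMeasurement(
                    plate_id=plate_id,
                    vesicle_id=vesicle_id,
                    well=_WELL_NAMES[cursor],
                    sample_id=sample_id,
                    role=role,
                    group=group,
                    emission=max(emission, 0.0),
                )
            )
            cursor += 1

        for _ in range(cfg.n_neg_controls):
            add_well("", "neg_control", "none", 0.0)
        for _ in range(cfg.n_pos_controls):
            add_well("", "pos_control", "none", 100.0)
        for sid, f in zip(sera, latents):
            for _ in range(cfg.replicate_count):
                add_well(sid, "sample", cfg.groups[0], float(f))
        plate = Plate(plate_id, vesicle_id, wells, cfg.replicate_count)
        plate.validate()
        plates.append(plate)
    return plates


def shuffle_group_labels(cohort: list[Plate], seed: int) -> list[Plate]:
    """Permute clinical group labels uniformly at random across sample sera.

    The multiset of labels is preserved (a serum count per group before
    equals the count after); emissions and every other field are untouched.
    Deterministic given ``seed``.
    """
    from .plate_model import relabel_wells

    seen: dict[str, str] = {}
    for plate in cohort:
        for w in plate.wells:
            if w.role == "sample" and w.sample_id not in seen:
                seen[w.sample_id] = w.group
    if not seen:
        raise ConfigError("cohort has no labeled sample sera to shuffle")
    sample_ids = list(seen)
    labels = np.array([seen[s] for s in sample_ids], dtype=object)
    rng = np.random.default_rng(seed)
    shuffled = labels[rng.permutation(len(labels))]
    mapping = dict(zip(sample_ids, shuffled))
    return [relabel_wells(p, mapping) for p in cohort]
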