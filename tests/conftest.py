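"""Shared fixtures: synthetic cohorts, feature matrices, and plate builders."""

from __future__ import annotations

import dataclasses

import pandas as pd
import pytest

import reactomics as rx


@pytest.fixture(scope="session")
def default_cfg() -> rx.SyntheticConfig:
    return rx.default_study_config(seed=1)


@pytest.fixture(scope="session")
def cohort(default_cfg) -> list[rx.Plate]:
    return rx.generate_cohort(default_cfg)


@pytest.fixture(scope="session")
def features(cohort) -> rx.FeatureMatrix:
    """Standardized + normalized feature matrix of the default cohort."""
    return rx.build_features(cohort)


@pytest.fixture(scope="session")
def small_panel() -> rx.PanelSpec:
    return rx.PanelSpec(
        vesicles=(
            rx.VesicleSpec("v1", "DMPC/PDA", "2:3", 8.0),
            rx.VesicleSpec("v2", "DOPC/PDA", "2:3", 7.4),
        )
    )


@pytest.fixture(scope="session")
def tiny_cfg(small_panel) -> rx.SyntheticConfig:
    """Two groups x 3 sera on a two-vesicle panel; fits one plate per vesicle."""
    effect = pd.DataFrame(
        {"v1": [60.0, 40.0], "v2": [55.0, 45.0]}, index=["control", "stomach"]
    )
    return rx.SyntheticConfig(
        panel=small_panel,
        group_effect=effect,
        groups=("control", "stomach"),
        n_per_group=3,
        seed=11,
    )


def make_plate(
    plate_id: str = "p1",
    vesicle_id: str = "v1",
    neg=(10.0, 10.0, 10.0),
    pos=(110.0, 110.0, 110.0),
    samples: dict[str, tuple[str, tuple[float, ...]]] | None = None,
    standards: dict[str, tuple[float, ...]] | None = None,
    replicate_count: int = 3,
) -> rx.Plate:
    """Hand-build a validated plate from explicit well emissions."""
    wells = []
    names = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]
    cursor = 0

    def add(sample_id, role, group, emission):
        nonlocal cursor
        wells.append(
            rx.WellMeasurement(plate_id, vesicle_id, names[cursor],
                               sample_id, role, group, float(emission))
        )
        cursor += 1

    for e in neg:
        add("", "neg_control", "none", e)
    for e in pos:
        add("", "pos_control", "none", e)
    for sid, ems in (standards or {}).items():
        for e in ems:
            add(sid, "standard", "none", e)
    for sid, (group, ems) in (samples or {}).items():
        for e in ems:
            add(sid, "sample", group, e)
    plate = rx.Plate(plate_id, vesicle_id, wells, replicate_count)
    plate.validate()
    return plate


@pytest.fixture
def plate_builder():
    return make_plate


def scale_effect(cfg: rx.SyntheticConfig, scale: float) -> rx.SyntheticConfig:
    """Shrink/expand group separation around the control profile."""
    control = cfg.group_effect.loc["control"]
    effect = control + (cfg.group_effect - control) * scale
    return dataclasses.replace(cfg, group_effect=effect)


@pytest.fixture(scope="session")
def zero_effect_features() -> rx.FeatureMatrix:
    """Default-sized cohort in which all groups share one latent profile."""
    cfg = scale_effect(rx.default_study_config(seed=5), 0.0)
    return rx.build_features(rx.generate_cohort(cfg))


@pytest.fixture(scope="session")
def shuffle_null_report(features) -> rx.ShuffleReport:
    """20-shuffle label-permutation null on the default cohort (shared:
    this is the most expensive fixture in the suite)."""
    return rx.run_shuffle_null(
        features, "pancreas", "control", seeds=list(range(101, 121))
    )
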