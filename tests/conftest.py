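"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import dataclasses
from typing import List, Sequence

import numpy as np
import pytest

from lumitrack.config import (
    MixtureConfig,
    MobilityConfig,
    OpticsConfig,
    PopulationConfig,
)
from lumitrack.quantify import Detection
from lumitrack.simgen import CellTruth


@pytest.fixture
def optics() -> OpticsConfig:
    return OpticsConfig()


@pytest.fixture
def small_population() -> PopulationConfig:
    """A small, fast population on a compact field."""
    return PopulationConfig(
        n_cells=60,
        field_size=(640, 640),
        min_separation=20.0,
        mixture=MixtureConfig(p_responder=0.5),
        mobility=MobilityConfig(p_lost=0.1, p_displaced=0.1),
        seed=7,
    )


def make_detections(coords: Sequence[tuple], intensities=None) -> List[Detection]:
    """Build bare detections from (x, y) coordinates."""
    if intensities is None:
        intensities = [1000.0] * len(coords)
    return [
        Detection(det_id=i, centroid=(float(x), float(y)), intensity=float(v), area=177)
        for i, ((x, y), v) in enumerate(zip(coords, intensities))
    ]


def detections_from_truth(cells: Sequence[CellTruth], timepoint: str) -> List[Detection]:
    """Idealised detections taken straight from planted truth positions."""
    dets = []
    k = 0
    for c in cells:
        pos = c.pos_t0 if timepoint == "t0" else c.pos_t1
        if pos is None:
            continue
        rate = c.rate_t0 if timepoint == "t0" else c.rate_t1
        dets.append(
            Detection(
                det_id=k, centroid=pos, intensity=float(rate), area=177,
                channel="truth", timepoint=timepoint,
            )
        )
        k += 1
    return dets
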