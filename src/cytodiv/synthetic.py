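"""Synthetic multi-sample cytometry datasets with known ground truth.

Each sample is a Gaussian-mixture event cloud on the configured channels
plus a tight internal-standard bead population that is identical across
samples *before* acquisition drift; drift is modeled as a pure
per-sample translation added to every event (matching the correction
model the normalization module inverts).  Per-sample analyzed volumes
and dilution factors exercise the volume-correction stage.  Events are
simulated directly on the post-transform scale by default, so pipelines
can run with the asinh step disabled; a raw-scale mode (sinh
back-transformed with a known cofactor) supports cofactor-recovery
tests.

:func:`make_fixture_suite` writes the canned scenarios the test suite
and the acceptance script share, each with FCS files, a ready-to-run
config.yaml and a truth.json.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fcs import EventTable, write_fcs

__all__ = [
    "Subpopulation",
    "SampleTruth",
    "SimulationTruth",
    "simulate_dataset",
    "simulate_sample",
    "make_fixture_suite",
    "write_fcs",
]

DEFAULT_CHANNELS = ["FL1-H", "SSC-H"]
BEAD_MEAN = 3000.0
BEAD_STD = 5.0


@dataclass
class Subpopulation:
    mean: tuple[float, ...]
    std: tuple[float, ...]
    n: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("subpopulation count must be positive")
        if any(s <= 0 for s in self.std):
            raise ValueError("subpopulation std must be positive (degenerate covariance)")


@dataclass
class SampleTruth:
    sample_id: str
    subpops: list[Subpopulation]
    shift: tuple[float, ...]  # per-channel acquisition drift added to ALL events
    true_volume: float = 1.0
    dilution_factor: float = 1.0


@dataclass
class SimulationTruth:
    channels: list[str]
    samples: list[SampleTruth]
    bead_mean: tuple[float, ...]
    bead_std: tuple[float, ...]
    bead_n: int
    seed: int
    raw_scale_cofactors: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.bead_n <= 0:
            raise ValueError("bead count must be positive")
        if any(s <= 0 for s in self.bead_std):
            raise ValueError("bead std must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def simulate_sample(
    truth: SimulationTruth, sample: SampleTruth, rng: np.random.Generator
) -> EventTable:
    """Draw one sample: mixture events + beads, then the drift shift."""
    blocks = []
    for sp in sample.subpops:
        blocks.append(
            rng.normal(loc=sp.mean, scale=sp.std, size=(sp.n, len(truth.channels)))
        )
    blocks.append(
        rng.normal(loc=truth.bead_mean, scale=truth.bead_std,
                   size=(truth.bead_n, len(truth.channels)))
    )
    events = np.vstack(blocks) + np.asarray(sample.shift)[None, :]
    if truth.raw_scale_cofactors:
        for i, ch in enumerate(truth.channels):
            c = truth.raw_scale_cofactors.get(ch)
            if c:
                events[:, i] = c * np.sinh(events[:, i])
    return EventTable(
        sample_id=sample.sample_id,
        events=events,
        channel_names=list(truth.channels),
        true_volume=sample.true_volume,
        dilution_factor=sample.dilution_factor,
    )


def simulate_dataset(truth: SimulationTruth) -> list[EventTable]:
    """All samples of a scenario; reproducible given ``truth.seed``."""
    rng = np.random.default_rng(truth.seed)
    return [simulate_sample(truth, s, rng) for s in truth.samples]


# ---------------------------------------------------------------------------
# Canned scenarios
# ---------------------------------------------------------------------------

_BASE_POPS = [
    Subpopulation(mean=(300.0, 300.0), std=(60.0, 60.0), n=5000),
    Subpopulation(mean=(800.0, 500.0), std=(60.0, 60.0), n=3000),
    Subpopulation(mean=(500.0, 900.0), std=(60.0, 60.0), n=2000),
]


def _scale(pops: list[Subpopulation], factor: float) -> list[Subpopulation]:
    return [
        Subpopulation(mean=p.mean, std=p.std, n=max(1, int(round(p.n * factor))))
        for p in pops
    ]


def _scenario_truths(seed: int) -> dict[str, SimulationTruth]:
    ch = DEFAULT_CHANNELS
    bead = dict(bead_mean=(BEAD_MEAN, BEAD_MEAN), bead_std=(BEAD_STD, BEAD_STD))
    zero = (0.0, 0.0)

    disjoint_a = [
        Subpopulation(mean=(300.0, 300.0), std=(40.0, 40.0), n=4000),
        Subpopulation(mean=(400.0, 700.0), std=(40.0, 40.0), n=3000),
    ]
    disjoint_b = [
        Subpopulation(mean=(1300.0, 1300.0), std=(40.0, 40.0), n=4000),
        Subpopulation(mean=(1600.0, 1000.0), std=(40.0, 40.0), n=3000),
    ]

    return {
        "identical-pair": SimulationTruth(
            channels=ch, seed=seed, bead_n=500, **bead,
            samples=[
                SampleTruth("A", _BASE_POPS, zero),
                SampleTruth("B", _BASE_POPS, zero),
            ],
        ),
        "disjoint-pair": SimulationTruth(
            channels=ch, seed=seed + 1, bead_n=500, **bead,
            samples=[
                SampleTruth("A", disjoint_a, zero),
                SampleTruth("B", disjoint_b, zero),
            ],
        ),
        "nested-pair": SimulationTruth(
            channels=ch, seed=seed + 2, bead_n=500, **bead,
            samples=[
                SampleTruth("A", _BASE_POPS, zero),
                SampleTruth("B", _scale(_BASE_POPS, 0.5), zero),
            ],
        ),
        "drifted-with-beads": SimulationTruth(
            channels=ch, seed=seed + 3, bead_n=500, **bead,
            samples=[
                SampleTruth("S1", _BASE_POPS, (100.0, -100.0)),
                SampleTruth("S2", _BASE_POPS, (0.0, 0.0)),
                SampleTruth("S3", _BASE_POPS, (-100.0, 100.0)),
            ],
        ),
        "dilution-series": SimulationTruth(
            channels=ch, seed=seed + 4, bead_n=500, **bead,
            samples=[
                SampleTruth("V05", _BASE_POPS, zero, true_volume=0.5),
                SampleTruth("V10", _BASE_POPS, zero, true_volume=1.0),
                SampleTruth("V20", _BASE_POPS, zero, true_volume=2.0),
            ],
        ),
    }


FIVE_BLOB_CENTERS = [(0.0, 0.0), (8.0, 0.0), (0.0, 8.0), (8.0, 8.0), (16.0, 4.0)]
FIVE_BLOB_SIGMA = 0.1
FIVE_BLOB_N = 100


def five_blob_points(seed: int) -> np.ndarray:
    """The five-blob clustering set: 5 tight, well-separated 2-D blobs."""
    rng = np.random.default_rng(seed)
    return np.vstack([
        rng.normal(loc=c, scale=FIVE_BLOB_SIGMA, size=(FIVE_BLOB_N, 2))
        for c in FIVE_BLOB_CENTERS
    ])


def _write_config(outdir: Path, truth: SimulationTruth) -> Path:
    cfg = {
        "samples": [
            {
                "id": s.sample_id,
                "file": f"{s.sample_id}.fcs",
                "volume": s.true_volume,
                "dilution": s.dilution_factor,
            }
            for s in truth.samples
        ],
        "channels": list(truth.channels),
        "gates": {
            "target": {
                "kind": "rectangle",
                "channels": {c: [-600.0, 2400.0] for c in truth.channels},
            },
            "beads": {
                "kind": "rectangle",
                "channels": {c: [2600.0, 3400.0] for c in truth.channels},
            },
        },
        "target_gate": "target",
        "bead_gate": "beads",
        "normalization": {"enabled": True, "asinh": {"enabled": False}},
        "binning": {"mode": "dynamic", "nbins": "auto"},
        "diversity": {"beta": "bray", "transform": None},
        "ordination": {"kmin": 2, "kmax": 10, "restarts": 20, "seed": truth.seed},
        "masking": {"channel_pair": list(truth.channels[:2])},
    }
    path = outdir / "config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path


def make_fixture_suite(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write every canned scenario under ``outdir``; returns name -> dir.

    Same seed, same bytes: FCS fixtures are byte-identical across calls.
    """
    outdir = Path(outdir)
    paths: dict[str, Path] = {}
    for name, truth in _scenario_truths(seed).items():
        d = outdir / name
        d.mkdir(parents=True, exist_ok=True)
        for table in simulate_dataset(truth):
            write_fcs(table, d / f"{table.sample_id}.fcs")
        (d / "truth.json").write_text(truth.to_json())
        _write_config(d, truth)
        paths[name] = d

    d = outdir / "five-blob"
    d.mkdir(parents=True, exist_ok=True)
    pts = five_blob_points(seed + 5)
    np.savetxt(d / "points.csv", pts, delimiter=",", header="x,y", comments="")
    (d / "truth.json").write_text(json.dumps({
        "k": len(FIVE_BLOB_CENTERS),
        "centers": FIVE_BLOB_CENTERS,
        "sigma": FIVE_BLOB_SIGMA,
        "n_per_blob": FIVE_BLOB_N,
        "seed": seed + 5,
    }, indent=2))
    paths["five-blob"] = d
    return paths
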