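"""End-to-end workflow orchestration.

The pipeline runs read -> gate -> (normalize) -> ranges -> bin count
(auto or fixed) -> contingency -> vectorize -> volume-correct ->
(standardize) -> alpha -> beta (+ Bray partition) -> nMDS -> bin scores
-> cluster-count selection -> K-means -> mask -> overlays, and writes
every intermediate artifact as plain CSV (+ JSON metadata) so stages are
individually runnable and diffable.  The monolithic :func:`run` calls
the exact same stage functions the CLI subcommands call, so stage-wise
chaining reproduces its outputs byte for byte.

All randomness (nMDS restarts, K-means seeding) funnels through the
single configured seed recorded in the run manifest.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binning import (
    CountMatrix,
    build_contingency,
    build_count_matrix,
    compute_ranges,
    optimal_bins,
)
from .diversity import alpha_table, distance_matrix, DistanceMatrix, transform_counts
from .errors import ConfigError
from .fcs import EventTable, RunConfig, apply_gate, read_fcs
from .masking import build_mask, overlay
from .normalization import (
    CofactorTable,
    asinh_transform,
    compute_bead_shifts,
    estimate_asinh_cofactors,
    translate_events,
)
from .ordination import bin_scores, choose_k, nmds

# %.17g round-trips float64 exactly, so re-loading a stage's CSV output
# reproduces the in-memory values bit for bit (stage chaining == monolithic)
FLOAT_FMT = "%.17g"


@dataclass
class RunResult:
    outdir: Path
    counts: CountMatrix
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Stage: read + gate + normalize + bin
# ---------------------------------------------------------------------------

def load_gated_tables(cfg: RunConfig) -> tuple[list[EventTable], pd.DataFrame | None]:
    """Read every sample, normalize (if enabled) and apply the target gate.

    Returns the analysis-ready tables plus a provenance frame of bead
    means / shifts / cofactors (None when normalization is disabled).
    Shifts are computed from bead events of the *ungated* file, then
    applied to the target-gated events: beads are internal standards and
    normally sit outside the target gate.
    """
    raw = [
        read_fcs(s.file, sample_id=s.sample_id, true_volume=s.volume,
                 dilution_factor=s.dilution) for s in cfg.samples
    ]
    target = cfg.gates[cfg.target_gate]
    gated = [apply_gate(t, target) for t in raw]

    prov = None
    norm = cfg.normalization
    if norm.get("enabled", True) and cfg.bead_gate:
        bead_gate = cfg.gates[cfg.bead_gate]
        beads = [apply_gate(t, bead_gate) for t in raw]
        shifts = compute_bead_shifts(beads, cfg.channels)
        gated = [
            translate_events(t, shifts.shifts_for(t.sample_id)) for t in gated
        ]
        rows = [
            {
                "channel": ch,
                "sample": s,
                "bead_mean": shifts.bead_means[i, j],
                "shift": shifts.shifts[i, j],
            }
            for i, ch in enumerate(shifts.channels)
            for j, s in enumerate(shifts.samples)
        ]
        prov = pd.DataFrame(rows)

    asinh_cfg = norm.get("asinh") or {}
    if asinh_cfg.get("enabled", False):
        user = asinh_cfg.get("cofactors")
        if user:
            cof = CofactorTable(
                cofactors={ch: float(user[ch]) for ch in cfg.channels}, method="user"
            )
        else:
            cof = estimate_asinh_cofactors(
                gated, cfg.channels, candidate_grid=asinh_cfg.get("grid")
            )
        gated = [asinh_transform(t, cof) for t in gated]
        if prov is None:
            prov = pd.DataFrame({"channel": cfg.channels})
        prov["cofactor"] = prov["channel"].map(cof.cofactors)
    return gated, prov


def stage_bin(
    cfg: RunConfig, outdir: Path, nbins: int | None = None
) -> tuple[CountMatrix, list[EventTable]]:
    """Bin all samples onto a common grid; writes counts.csv + metadata."""
    outdir.mkdir(parents=True, exist_ok=True)
    tables, prov = load_gated_tables(cfg)
    bcfg = cfg.binning
    ranges = compute_ranges(
        tables, cfg.channels, mode=bcfg.get("mode", "dynamic"),
        fixed_limits=bcfg.get("limits"),
    )
    if nbins is None:
        configured = bcfg.get("nbins", "auto")
        nbins = optimal_bins(tables, cfg.channels) if configured in (None, "auto") \
            else int(configured)
    grids = [build_contingency(t, ranges, nbins, cfg.channels) for t in tables]
    counts = build_count_matrix(grids, [t.true_volume for t in tables])

    coords = counts.midpoints()
    frame = pd.DataFrame(coords, columns=[f"mid_{c}" for c in counts.channels])
    for j, s in enumerate(counts.samples):
        frame[s] = counts.F[:, j]
    frame.to_csv(outdir / "counts.csv", index=False, float_format=FLOAT_FMT)
    pd.DataFrame(
        {"sample": counts.samples, "out_of_range": [g.out_of_range for g in grids]}
    ).to_csv(outdir / "out_of_range.csv", index=False)
    if prov is not None:
        prov.to_csv(outdir / "provenance.csv", index=False, float_format=FLOAT_FMT)
    meta = {
        "channels": counts.channels,
        "samples": counts.samples,
        "nbins": counts.nbins,
        "range_mode": ranges.mode,
        "breakpoints": {c: list(map(float, b))
                        for c, b in zip(counts.channels, counts.breakpoints)},
        "volumes": list(map(float, counts.volumes)),
        "d": list(map(float, counts.d)),
        "W_column_sums": list(map(float, counts.W.sum(axis=0))),
    }
    (outdir / "counts_meta.json").write_text(json.dumps(meta, indent=2))
    return counts, tables


def load_counts(outdir: Path) -> CountMatrix:
    """Reload a CountMatrix written by :func:`stage_bin`."""
    outdir = Path(outdir)
    meta = json.loads((outdir / "counts_meta.json").read_text())
    frame = pd.read_csv(outdir / "counts.csv", float_precision="round_trip")
    F = frame[meta["samples"]].to_numpy(dtype=float)
    d = np.asarray(meta["d"], dtype=float)
    from itertools import product

    index = list(product(*(range(meta["nbins"]) for _ in meta["channels"])))
    return CountMatrix(
        samples=list(meta["samples"]),
        channels=list(meta["channels"]),
        breakpoints=[np.asarray(meta["breakpoints"][c]) for c in meta["channels"]],
        bin_index=index,
        W=F / d[None, :],
        F=F,
        volumes=np.asarray(meta["volumes"], dtype=float),
        d=d,
    )


# ---------------------------------------------------------------------------
# Stage: diversity
# ---------------------------------------------------------------------------

def stage_diversity(counts: CountMatrix, cfg_div: dict, outdir: Path) -> dict[str, DistanceMatrix]:
    """Alpha + beta tables from the volume-corrected count matrix."""
    outdir.mkdir(parents=True, exist_ok=True)
    F = counts.F
    method = cfg_div.get("transform")
    if method:
        F = transform_counts(F, method)
    alpha = alpha_table(F, counts.samples)
    alpha.frame.to_csv(outdir / "alpha.csv", index_label="sample",
                       float_format=FLOAT_FMT)
    index = cfg_div.get("beta", "bray")
    mats = distance_matrix(F, counts.samples, index=index)
    for key, dm in mats.items():
        name = "beta_bray" if key == "bray" else (
            f"beta_bray_{key}" if key in ("balanced", "gradient") else f"beta_{key}"
        )
        dm.to_frame().to_csv(outdir / f"{name}.csv", index_label="sample",
                             float_format=FLOAT_FMT)
    return mats


def load_distance(path: Path, index_name: str = "bray") -> DistanceMatrix:
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return DistanceMatrix(labels=list(frame.index), values=frame.to_numpy(),
                          index_name=index_name)


# ---------------------------------------------------------------------------
# Stage: ordination
# ---------------------------------------------------------------------------

def stage_ordinate(
    D: DistanceMatrix, counts: CountMatrix, cfg_ord: dict, outdir: Path,
    seed: int | None = None,
) -> dict:
    """nMDS + bin scores + cluster-count selection; writes score tables."""
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg_ord.get("seed", 0)) if seed is None else int(seed)
    result = nmds(
        D, dims=2, seed=seed, restarts=int(cfg_ord.get("restarts", 20))
    )
    scores = bin_scores(result, counts.F)
    sel = choose_k(
        scores,
        kmin=int(cfg_ord.get("kmin", 2)),
        kmax=int(cfg_ord.get("kmax", 10)),
        seed=seed,
        rule=cfg_ord.get("ch_rule", "max"),
    )
    model = sel.models[sel.K]

    pd.DataFrame(
        result.sample_scores, columns=["NMDS1", "NMDS2"], index=result.sample_labels
    ).to_csv(outdir / "nmds_samples.csv", index_label="sample",
             float_format=FLOAT_FMT)

    placed = ~np.isnan(scores).any(axis=1)
    cluster_col = np.full(len(scores), -1.0)
    cluster_col[placed] = model.assignments
    bins_frame = pd.DataFrame(scores, columns=["NMDS1", "NMDS2"])
    for k, ch in enumerate(counts.channels):
        bins_frame[f"bin_{ch}"] = [idx[k] for idx in counts.bin_index]
    bins_frame["cluster"] = cluster_col.astype(int)  # -1 = unplaced all-zero bin
    bins_frame.to_csv(outdir / "nmds_bins.csv", index_label="bin",
                      float_format=FLOAT_FMT)
    sel.table.to_csv(outdir / "k_selection.csv", index=False,
                     float_format=FLOAT_FMT)
    meta = {
        "stress": result.stress,
        "seed": seed,
        "restarts": result.n_restarts,
        "converged": result.converged,
        "K": sel.K,
    }
    (outdir / "ordination_meta.json").write_text(json.dumps(meta, indent=2))
    return {"nmds": result, "bin_scores": scores, "selection": sel, "model": model,
            "placed": placed}


# ---------------------------------------------------------------------------
# Stage: mask + overlays
# ---------------------------------------------------------------------------

def stage_mask(
    counts: CountMatrix, bin_clusters: np.ndarray, cfg_mask: dict,
    tables: list[EventTable], outdir: Path,
) -> None:
    """Single mask over the configured channel pair + per-sample overlays."""
    outdir.mkdir(parents=True, exist_ok=True)
    pair = cfg_mask.get("channel_pair") or counts.channels[:2]
    mask = build_mask(bin_clusters, counts, tuple(pair))
    mask.to_frame().to_csv(outdir / "mask_labels.csv", index=False)
    try:
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap  # noqa: F401
        fig_ok = True
    except Exception:  # pragma: no cover
        fig_ok = False
    if fig_ok:
        _render_mask_png(mask, outdir / "mask.png")
        for t in tables:
            overlay(t, mask, outdir / f"overlay_{t.sample_id}.png")


def _render_mask_png(mask, path: Path) -> None:
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    ids = sorted(mask.palette)
    lut = [(1, 1, 1, 1)] + [mask.palette[c] for c in ids]
    remap = np.zeros((max(ids) + 1) if ids else 1, dtype=int)
    for pos, cid in enumerate(ids, start=1):
        remap[cid] = pos
    shown = remap[mask.labels] if ids else mask.labels
    bx, by = mask.breakpoints
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(shown.T, origin="lower", cmap=ListedColormap(lut),
              vmin=0, vmax=len(ids), aspect="auto", interpolation="nearest",
              extent=(bx[0], bx[-1], by[0], by[-1]))
    ax.set_xlabel(mask.channel_pair[0])
    ax.set_ylabel(mask.channel_pair[1])
    ax.set_title("bin-cluster mask")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Monolithic run
# ---------------------------------------------------------------------------

def run(
    cfg: RunConfig, outdir: str | Path, nbins: int | None = None,
    seed: int | None = None,
) -> RunResult:
    """Execute the whole workflow and write a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": int(cfg.ordination.get("seed", 0)) if seed is None else int(seed),
        "applied_defaults": cfg.applied_defaults,
        "stages": {},
        "warnings": [],
        "outputs": [],
    }

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest["stages"][name] = round(time.perf_counter() - self.t0, 4)

        return _T()

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        with timed("bin"):
            counts, tables = stage_bin(cfg, outdir, nbins=nbins)
        with timed("diversity"):
            mats = stage_diversity(counts, cfg.diversity, outdir)
        with timed("ordinate"):
            key = "bray" if "bray" in mats else next(iter(mats))
            ord_out = stage_ordinate(mats[key], counts, cfg.ordination, outdir,
                                     seed=seed)
        with timed("mask"):
            cluster_col = np.full(len(ord_out["bin_scores"]), np.nan)
            cluster_col[ord_out["placed"]] = ord_out["model"].assignments
            stage_mask(counts, cluster_col, cfg.masking, tables, outdir)
    manifest["warnings"] = [str(w.message) for w in caught]
    manifest["outputs"] = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest["stress"] = ord_out["nmds"].stress
    manifest["K"] = ord_out["selection"].K
    manifest["nbins"] = counts.nbins
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunResult(outdir=outdir, counts=counts, manifest=manifest)
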