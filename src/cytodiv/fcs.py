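"""FCS list-mode input/output, gating, and run-configuration parsing.

Implements a minimal but standards-conforming codec for FCS 3.0/3.1
list-mode files (the format produced by essentially every cytometer):
a 58-byte ASCII header with segment offsets, a delimited TEXT segment of
``$KEY value`` pairs (delimiter escaping by doubling), and a DATA segment
of packed event values.  Only list mode (``$MODE L``) is supported, with
float (``F``), double (``D``) and unsigned integer (``I``) datatypes.

Gates are declared in the run configuration rather than imported from
acquisition-software workspaces: rectangles over any number of channels
and simple polygons over exactly two.  The boundary convention is closed
on the low edge and open on the high edge (``[low, high)``), matching the
half-open binning convention downstream; polygon boundary points count as
inside.
"""

from __future__ import annotations

import os
import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
import yaml

from .errors import ConfigError, FormatError, IntegrityError

__all__ = [
    "EventTable",
    "Gate",
    "RunConfig",
    "SampleSpec",
    "read_fcs",
    "write_fcs",
    "apply_gate",
    "read_config",
]


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

@dataclass
class EventTable:
    """Events x channels matrix for one sample, plus acquisition metadata.

    ``true_volume`` is the real volume analyzed after correcting for
    dilutions of any nature (units arbitrary but consistent across the
    sample set); ``dilution_factor`` >= 1 records the dilution applied
    before acquisition.
    """

    sample_id: str
    events: np.ndarray
    channel_names: list[str]
    true_volume: float = 1.0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2:
            raise ValueError("events must be a 2-D array (events x channels)")
        self.channel_names = list(self.channel_names)
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.events.shape[1] != len(self.channel_names):
            raise ValueError(
                f"events has {self.events.shape[1]} columns but "
                f"{len(self.channel_names)} channel names were given"
            )
        if np.isnan(self.events).any():
            raise ValueError("events contains missing values")
        if not self.true_volume > 0:
            raise ValueError("true_volume must be positive")
        if not self.dilution_factor >= 1:
            raise ValueError("dilution_factor must be >= 1")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's values as a 1-D array."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ConfigError(
                f"sample {self.sample_id!r}: unknown channel {name!r}; "
                f"available: {self.channel_names}"
            ) from None
        return self.events[:, idx]

    def with_events(self, events: np.ndarray) -> "EventTable":
        """Copy of this table with the event matrix replaced, metadata kept."""
        return replace(self, events=events)


# ---------------------------------------------------------------------------
# Gates
# ---------------------------------------------------------------------------

@dataclass
class Gate:
    """A region of channel space selecting a population of events.

    kind="rectangle": ``borders`` maps each channel to a (low, high) pair
    and may span any number of channels.  kind="polygon": ``channels``
    names exactly two channels and ``vertices`` is the ordered vertex
    list of a simple polygon in that plane.
    """

    gate_id: str
    kind: str
    channels: list[str]
    borders: dict[str, tuple[float, float]] | None = None
    vertices: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.kind == "rectangle":
            if not self.borders:
                raise ConfigError(f"gate {self.gate_id!r}: rectangle needs borders")
            self.channels = list(self.borders)
            for ch, (lo, hi) in self.borders.items():
                if not lo < hi:
                    raise ConfigError(
                        f"gate {self.gate_id!r}, channel {ch!r}: "
                        f"low ({lo}) must be < high ({hi})"
                    )
        elif self.kind == "polygon":
            if len(self.channels) != 2:
                raise ConfigError(
                    f"gate {self.gate_id!r}: polygon gates span exactly 2 channels"
                )
            if self.vertices is None or len(self.vertices) < 3:
                raise ConfigError(f"gate {self.gate_id!r}: polygon needs >= 3 vertices")
            poly = shapely.Polygon(self.vertices)
            if not poly.is_simple or poly.area == 0:
                raise ConfigError(
                    f"gate {self.gate_id!r}: polygon must be simple and non-degenerate"
                )
        else:
            raise ConfigError(f"gate {self.gate_id!r}: unknown kind {self.kind!r}")

    def contains(self, table: EventTable) -> np.ndarray:
        """Boolean mask of events inside the gate."""
        if self.kind == "rectangle":
            mask = np.ones(table.n_events, dtype=bool)
            for ch, (lo, hi) in self.borders.items():
                v = table.channel(ch)
                mask &= (v >= lo) & (v < hi)
            return mask
        x = table.channel(self.channels[0])
        y = table.channel(self.channels[1])
        poly = shapely.Polygon(self.vertices)
        # covers() includes the boundary, per the gate convention
        return shapely.covers(poly, shapely.points(x, y))


def apply_gate(table: EventTable, gate: Gate) -> EventTable:
    """Return the events of ``table`` inside ``gate``; metadata preserved.

    Event order is preserved.  An empty result is not an error (a warning
    is emitted): an empty gate is a legitimate, if suspicious, outcome.
    """
    mask = gate.contains(table)
    if not mask.any():
        warnings.warn(
            f"gate {gate.gate_id!r} retained no events of sample "
            f"{table.sample_id!r}",
            stacklevel=2,
        )
    return table.with_events(table.events[mask])


# ---------------------------------------------------------------------------
# FCS codec
# ---------------------------------------------------------------------------

_SUPPORTED_VERSIONS = (b"FCS3.0", b"FCS3.1")
_DELIM = b"/"

_DTYPES = {
    ("F", 32): "f4",
    ("D", 64): "f8",
    ("I", 16): "u2",
    ("I", 32): "u4",
}
_BYTEORD = {"1,2,3,4": "<", "4,3,2,1": ">", "2,1": "<", "1,2": "<"}


def _parse_text(raw: bytes) -> dict[str, str]:
    """Parse a delimited TEXT segment; doubled delimiters are literals."""
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[:1]
    body = raw[1:]
    tokens: list[bytes] = []
    cur = bytearray()
    i = 0
    n = len(body)
    while i < n:
        c = body[i : i + 1]
        if c == delim:
            if body[i + 1 : i + 2] == delim:
                cur.extend(delim)
                i += 2
                continue
            tokens.append(bytes(cur))
            cur = bytearray()
            i += 1
        else:
            cur.extend(c)
            i += 1
    if cur:
        tokens.append(bytes(cur))
    if len(tokens) % 2:
        tokens = tokens[:-1] if not tokens[-1].strip() else tokens + [b""]
    out: dict[str, str] = {}
    for k, v in zip(tokens[::2], tokens[1::2]):
        out[k.decode("ascii", "replace").strip().upper()] = v.decode(
            "utf-8", "replace"
        )
    return out


def read_fcs(
    path: str | Path,
    sample_id: str | None = None,
    true_volume: float = 1.0,
    dilution_factor: float = 1.0,
) -> EventTable:
    """Read an FCS 3.0/3.1 list-mode file into an :class:`EventTable`.

    Volumes and dilutions come from the caller (typically the run config);
    a ``$VOL`` keyword, if present, is reported in a warning but not
    trusted, since acquisition software populates it inconsistently.

    Raises :class:`FormatError` for unsupported versions or datatypes and
    :class:`IntegrityError` when ``$TOT`` disagrees with the data segment.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FormatError(f"{path}: too short to be an FCS file")
    version = blob[:6]
    if version not in _SUPPORTED_VERSIONS:
        raise FormatError(
            f"{path}: unsupported FCS version {version.decode('ascii', 'replace')!r}"
        )

    def _off(a: int, b: int) -> int:
        s = blob[a:b].decode("ascii", "replace").strip()
        return int(s) if s else 0

    text_begin, text_end = _off(10, 18), _off(18, 26)
    data_begin, data_end = _off(26, 34), _off(34, 42)
    kw = _parse_text(blob[text_begin : text_end + 1])

    if data_begin == 0:
        data_begin = int(kw["$BEGINDATA"])
    if data_end == 0:
        data_end = int(kw["$ENDDATA"])

    mode = kw.get("$MODE", "L").upper()
    if mode != "L":
        raise FormatError(f"{path}: only list mode ($MODE L) is supported, got {mode}")

    n_par = int(kw["$PAR"])
    tot = int(kw["$TOT"])
    datatype = kw.get("$DATATYPE", "F").upper()
    bits = {int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)}
    if len(bits) != 1:
        raise FormatError(f"{path}: mixed $PnB widths are not supported")
    key = (datatype, bits.pop())
    if key not in _DTYPES:
        raise FormatError(f"{path}: unsupported $DATATYPE/$PnB combination {key}")
    order = _BYTEORD.get(kw.get("$BYTEORD", "1,2,3,4"))
    if order is None:
        raise FormatError(f"{path}: unsupported $BYTEORD {kw.get('$BYTEORD')!r}")
    dtype = np.dtype(order + _DTYPES[key])

    raw = blob[data_begin : data_end + 1]
    n_values = len(raw) // dtype.itemsize
    if n_values * dtype.itemsize != len(raw) or n_values != tot * n_par:
        raise IntegrityError(
            f"{path}: $TOT={tot} x $PAR={n_par} does not match data segment "
            f"({n_values} values present)"
        )
    events = np.frombuffer(raw, dtype=dtype).reshape(tot, n_par).astype(float)

    names = []
    for i in range(1, n_par + 1):
        names.append(kw.get(f"$P{i}N", f"P{i}"))
        amp = kw.get(f"$P{i}E", "0,0").split(",")
        if amp and float(amp[0]) != 0.0:
            warnings.warn(
                f"{path}: $P{i}E declares log amplification ({kw[f'$P{i}E']}); "
                "data are assumed preprocessed and are NOT de-logged",
                stacklevel=2,
            )
    if "$VOL" in kw:
        warnings.warn(
            f"{path}: $VOL keyword present ({kw['$VOL']}) but ignored; "
            "volumes are taken from the run configuration",
            stacklevel=2,
        )

    return EventTable(
        sample_id=sample_id or path.stem,
        events=events,
        channel_names=names,
        true_volume=true_volume,
        dilution_factor=dilution_factor,
    )


def write_fcs(table: EventTable, path: str | Path) -> Path:
    """Write ``table`` as a valid FCS 3.1 list-mode file (float32 data).

    ``$PnN`` is set from the channel names (delimiter characters escaped
    by doubling) and ``$TOT`` from the event count, so the file
    round-trips through :func:`read_fcs` to float32 precision.
    """
    path = Path(path)
    n_events, n_par = table.events.shape
    data = np.ascontiguousarray(table.events, dtype="<f4").tobytes()

    def esc(v: str) -> str:
        return v.replace(_DELIM.decode(), _DELIM.decode() * 2)

    kw: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"),
        ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"),
        ("$ENDSTEXT", "0"),
        ("$BEGINDATA", "{:>10d}"),
        ("$ENDDATA", "{:>10d}"),
        ("$NEXTDATA", "0"),
        ("$MODE", "L"),
        ("$DATATYPE", "F"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_events)),
    ]
    for i, name in enumerate(table.channel_names, start=1):
        hi = float(np.max(np.abs(table.events))) if n_events else 1.0
        kw += [
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}N", esc(name)),
            (f"$P{i}R", str(int(max(hi, 1.0)) + 1)),
        ]

    def render(begin: int, end: int) -> bytes:
        d = _DELIM.decode()
        parts = [d]
        for k, v in kw:
            if k in ("$BEGINDATA", "$ENDDATA"):
                v = v.format(begin if k == "$BEGINDATA" else end)
            parts.append(f"{k}{d}{v}{d}")
        return "".join(parts).encode("utf-8")

    text = render(0, 0)
    text_begin = 58
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data) - 1
    text = render(data_begin, data_end)  # fixed-width offsets: length unchanged

    header = b"FCS3.1    " + "".join(
        f"{v:>8d}"
        for v in (text_begin, text_end,
                  data_begin if data_begin <= 99_999_999 else 0,
                  data_end if data_end <= 99_999_999 else 0,
                  0, 0)
    ).encode("ascii")
    assert len(header) == 58
    path.write_bytes(header + text + data)
    return path


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class SampleSpec:
    sample_id: str
    file: Path
    volume: float = 1.0
    dilution: float = 1.0


@dataclass
class RunConfig:
    """Validated run configuration with defaults filled in."""

    samples: list[SampleSpec]
    channels: list[str]
    gates: dict[str, Gate]
    target_gate: str
    bead_gate: str | None = None
    normalization: dict = field(default_factory=dict)
    binning: dict = field(default_factory=dict)
    diversity: dict = field(default_factory=dict)
    ordination: dict = field(default_factory=dict)
    masking: dict = field(default_factory=dict)
    applied_defaults: list[str] = field(default_factory=list)


_DEFAULTS = {
    "normalization": {"enabled": True, "asinh": {"enabled": False}},
    "binning": {"mode": "dynamic", "nbins": "auto", "limits": None},
    "diversity": {
        "alpha": ["richness", "shannon", "simpson", "inv_simpson", "pielou"],
        "beta": "bray",
        "transform": None,
    },
    "ordination": {"kmin": 2, "kmax": 10, "restarts": 20, "seed": 0,
                   "ch_rule": "max"},
    "masking": {"channel_pair": None},
}


def _parse_gate(gate_id: str, raw: dict) -> Gate:
    kind = raw.get("kind", "rectangle")
    if kind == "rectangle":
        borders = {
            ch: (float(lo), float(hi)) for ch, (lo, hi) in raw["channels"].items()
        }
        return Gate(gate_id=gate_id, kind="rectangle", channels=list(borders),
                    borders=borders)
    return Gate(
        gate_id=gate_id,
        kind="polygon",
        channels=list(raw["channels"]),
        vertices=[tuple(map(float, v)) for v in raw["vertices"]],
    )


def read_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    All missing mandatory keys are reported at once.  Defaults filled in
    are recorded in ``RunConfig.applied_defaults`` so the run manifest can
    log them.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    missing = [k for k in ("samples", "channels", "target_gate") if k not in raw]
    if "target_gate" in raw and raw.get("target_gate") and "gates" not in raw:
        missing.append("gates")
    if missing:
        raise ConfigError(f"{path}: missing mandatory keys: {', '.join(missing)}")

    applied: list[str] = []
    samples = []
    for i, s in enumerate(raw["samples"]):
        f = Path(s["file"])
        if not f.is_absolute():
            f = path.parent / f
        if not f.exists():
            raise ConfigError(f"{path}: sample file not found: {f}")
        if "volume" not in s:
            applied.append(f"samples[{i}].volume=1.0")
        if "dilution" not in s:
            applied.append(f"samples[{i}].dilution=1.0")
        vol = float(s.get("volume", 1.0))
        dil = float(s.get("dilution", 1.0))
        if vol <= 0:
            raise ConfigError(f"{path}: sample {f.name}: volume must be positive")
        if dil < 1:
            raise ConfigError(f"{path}: sample {f.name}: dilution_factor must be >= 1")
        samples.append(
            SampleSpec(sample_id=s.get("id", f.stem), file=f, volume=vol, dilution=dil)
        )

    gates = {gid: _parse_gate(gid, g) for gid, g in (raw.get("gates") or {}).items()}
    target = raw["target_gate"]
    if target not in gates:
        raise ConfigError(f"{path}: target_gate {target!r} not defined under gates")
    bead = raw.get("bead_gate")
    if bead is not None and bead not in gates:
        raise ConfigError(f"{path}: bead_gate {bead!r} not defined under gates")

    sections = {}
    for section, defaults in _DEFAULTS.items():
        merged = dict(defaults)
        user = raw.get(section) or {}
        for k, v in user.items():
            merged[k] = v
        for k in defaults:
            if k not in user:
                applied.append(f"{section}.{k}={merged[k]!r}")
        sections[section] = merged

    cfg = RunConfig(
        samples=samples,
        channels=list(raw["channels"]),
        gates=gates,
        target_gate=target,
        bead_gate=bead,
        normalization=sections["normalization"],
        binning=sections["binning"],
        diversity=sections["diversity"],
        ordination=sections["ordination"],
        masking=sections["masking"],
        applied_defaults=applied,
    )

    # fail early if a configured channel is absent from any FCS file
    for spec in cfg.samples:
        names = _peek_channels(spec.file)
        for ch in cfg.channels:
            if ch not in names:
                raise ConfigError(
                    f"{path}: channel {ch!r} not present in sample "
                    f"{spec.sample_id!r} ({spec.file.name}); file has {names}"
                )
    return cfg


def _peek_channels(path: Path) -> list[str]:
    """Read only the TEXT segment of an FCS file and return $PnN names."""
    with open(path, "rb") as fh:
        head = fh.read(58)
        if len(head) < 58 or head[:6] not in _SUPPORTED_VERSIONS:
            raise FormatError(f"{path}: not a supported FCS file")
        tb, te = int(head[10:18]), int(head[18:26])
        fh.seek(tb)
        kw = _parse_text(fh.read(te - tb + 1))
    return [kw.get(f"$P{i}N", f"P{i}") for i in range(1, int(kw["$PAR"]) + 1)]
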