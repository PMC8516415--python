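"""Reading and writing PSG recordings (EDF) and hypnograms (CSV/text).

EDF reading is delegated to :mod:`mne`; each requested channel is read with
its own ``read_raw_edf`` call so that per-channel native sampling rates are
preserved (mne resamples mixed-rate channels to a common rate when they are
read together). Physical units are validated against the EDF signal header:
amplitude-dependent features assume microvolts, so only ``uV``/``µV`` (kept
as-is) and ``mV`` (converted ×1000) are accepted — anything else is an
error rather than a silent guess.

EDF writing exists only to materialise synthetic fixtures and uses a minimal
16-bit EDF encoder.

Hypnogram files are one stage token per epoch, either a bare text column or
a CSV with a ``stage`` column. Heterogeneous scoring vocabularies are mapped
to the canonical alphabet through a *dialect*: a token→stage mapping where
R&K stage 4 folds into N3 and movement/unknown tokens become unscored.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import numpy as np
import pandas as pd

from .core import STAGES, UNSCORED, Channel, Hypnogram, Recording, StageProbabilities

__all__ = [
    "read_recording",
    "write_recording_edf",
    "read_hypnogram",
    "write_hypnogram",
    "RK_DIALECT",
    "IDENTITY_DIALECT",
    "load_dialect",
]

# ---------------------------------------------------------------------------
# Stage-vocabulary dialects
# ---------------------------------------------------------------------------

#: Rechtschaffen & Kales numeric vocabulary (NSRR-style), stages 3 and 4 → N3.
RK_DIALECT: dict[str, str] = {
    "0": "W",
    "1": "N1",
    "2": "N2",
    "3": "N3",
    "4": "N3",
    "5": "R",
    "9": UNSCORED,
    "MOVEMENT": UNSCORED,
    "UNKNOWN": UNSCORED,
}

#: Canonical tokens map to themselves; the sentinel stays unscored.
IDENTITY_DIALECT: dict[str, str] = {s: s for s in STAGES} | {UNSCORED: UNSCORED}


def load_dialect(path: str | Path) -> dict[str, str]:
    """Load a token→stage dialect from a two-column ``token,stage`` config file."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'token,stage', got {line!r}")
        token, stage = parts
        if stage not in STAGES and stage != UNSCORED:
            raise ValueError(f"{path}:{lineno}: unknown canonical stage {stage!r}")
        mapping[token] = stage
    return mapping


# ---------------------------------------------------------------------------
# EDF reading
# ---------------------------------------------------------------------------

_UV_ALIASES = {"uv", "µv", "µv", "μv"}
_MV_ALIASES = {"mv"}


def _read_edf_signal_units(path: Path) -> dict[str, str]:
    """Parse per-signal physical-dimension strings straight from the EDF header."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise ValueError(f"{path}: not an EDF file (truncated header)")
        version = header[:8].decode("ascii", errors="replace").strip()
        if version != "0":
            raise ValueError(f"{path}: not an EDF file (version field {version!r})")
        ns = int(header[252:256].decode("ascii").strip())
        sig = fh.read(ns * 256)
    labels = [sig[16 * i : 16 * (i + 1)].decode("latin-1").strip() for i in range(ns)]
    off = ns * (16 + 80)
    dims = [sig[off + 8 * i : off + 8 * (i + 1)].decode("latin-1").strip() for i in range(ns)]
    return dict(zip(labels, dims))


def _unit_scale_to_uv(label: str, dim: str) -> float:
    d = dim.strip().lower()
    if d in _UV_ALIASES:
        return 1.0
    if d in _MV_ALIASES:
        return 1000.0
    raise ValueError(
        f"channel {label!r} has physical dimension {dim!r}; expected uV or mV "
        "(amplitude features require microvolt inputs)"
    )


def read_recording(path: str | Path, channel_spec: dict[str, str]) -> Recording:
    """Read requested channels from an EDF file into a :class:`Recording`.

    Parameters
    ----------
    path
        EDF/EDF+ file.
    channel_spec
        Mapping from role (``"EEG"``, ``"EOG"``, ``"EMG"``) to the channel
        label as it appears in the file, e.g. ``{"EEG": "C4-M1"}``.
    """
    import mne

    path = Path(path)
    units = _read_edf_signal_units(path)  # also validates the EDF magic
    available = list(units)
    channels: list[Channel] = []
    start_time = None
    for role, label in channel_spec.items():
        if label not in units:
            raise KeyError(
                f"channel {label!r} (role {role}) not found in {path.name}; "
                f"available channels: {available}"
            )
        _unit_scale_to_uv(label, units[label])  # reject unknown dimensions
        raw = mne.io.read_raw_edf(path, include=[label], preload=True, verbose="error")
        start_time = raw.info.get("meas_date")
        # mne folds uV/mV into volts internally, so volts → µV is always 1e6.
        data = raw.get_data(picks=[label])[0] * 1e6
        channels.append(Channel(label=label, role=role, samples=data, rate=float(raw.info["sfreq"])))
    return Recording(channels=channels, start_time=start_time)


# ---------------------------------------------------------------------------
# EDF writing (synthetic-fixture path only)
# ---------------------------------------------------------------------------


def _edf_field(value: object, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_recording_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF (one-second data records).

    Each channel's sample count must be an integer multiple of its rate and
    all channels must span the same whole number of seconds.
    """
    path = Path(path)
    n_records = None
    for c in rec.channels:
        spr = c.rate
        if abs(spr - round(spr)) > 1e-9:
            raise ValueError(f"channel {c.label}: non-integer samples per 1 s record")
        nrec = len(c.samples) / spr
        if abs(nrec - round(nrec)) > 1e-9:
            raise ValueError(f"channel {c.label}: duration is not a whole number of seconds")
        nrec = int(round(nrec))
        if n_records is None:
            n_records = nrec
        elif nrec != n_records:
            raise ValueError("channels must span identical durations for EDF export")
    assert n_records is not None

    ns = len(rec.channels)
    buf = _stdio.BytesIO()
    buf.write(_edf_field("0", 8))
    buf.write(_edf_field("X X X X", 80))
    buf.write(_edf_field("Startdate X X X X", 80))
    buf.write(_edf_field("01.01.00", 8))
    buf.write(_edf_field("00.00.00", 8))
    buf.write(_edf_field(256 * (1 + ns), 8))
    buf.write(_edf_field("", 44))
    buf.write(_edf_field(n_records, 8))
    buf.write(_edf_field(1, 8))
    buf.write(_edf_field(ns, 4))

    phys: list[tuple[float, float]] = []
    for c in rec.channels:
        amp = float(np.max(np.abs(c.samples))) if len(c.samples) else 1.0
        amp = max(amp, 1e-6)
        phys.append((-amp, amp))

    for c in rec.channels:
        buf.write(_edf_field(c.label, 16))
    for _ in rec.channels:
        buf.write(_edf_field("", 80))
    for _ in rec.channels:
        buf.write(_edf_field("uV", 8))
    for lo, _hi in phys:
        buf.write(_edf_field(f"{lo:.6g}"[:8], 8))
    for _lo, hi in phys:
        buf.write(_edf_field(f"{hi:.6g}"[:8], 8))
    for _ in rec.channels:
        buf.write(_edf_field(-32768, 8))
    for _ in rec.channels:
        buf.write(_edf_field(32767, 8))
    for _ in rec.channels:
        buf.write(_edf_field("", 80))
    for c in rec.channels:
        buf.write(_edf_field(int(round(c.rate)), 8))
    for _ in rec.channels:
        buf.write(_edf_field("", 32))

    digital: list[np.ndarray] = []
    for c, (lo, hi) in zip(rec.channels, phys):
        lo_f, hi_f = float(f"{lo:.6g}"[:8]), float(f"{hi:.6g}"[:8])
        gain = (32767 - (-32768)) / (hi_f - lo_f)
        dig = np.round((c.samples - lo_f) * gain + (-32768)).astype(np.int64)
        digital.append(np.clip(dig, -32768, 32767).astype("<i2"))

    for r in range(n_records):
        for c, dig in zip(rec.channels, digital):
            spr = int(round(c.rate))
            buf.write(dig[r * spr : (r + 1) * spr].tobytes())

    path.write_bytes(buf.getvalue())
    return path


# ---------------------------------------------------------------------------
# Hypnogram I/O
# ---------------------------------------------------------------------------

_PROB_COLUMNS = [f"p_{s}" for s in STAGES]


def read_hypnogram(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    epoch_len_s: float = 30.0,
) -> Hypnogram:
    """Read a hypnogram file and map its vocabulary to the canonical stages.

    Accepts either a headered CSV with a ``stage`` column (the format
    :func:`write_hypnogram` produces) or a bare one-token-per-line file.
    Unmapped tokens raise with the token and line number.
    """
    path = Path(path)
    dialect = dict(IDENTITY_DIALECT if dialect is None else dialect)
    text = path.read_text()
    first = text.splitlines()[0] if text.strip() else ""
    if "," in first and "stage" in [c.strip() for c in first.split(",")]:
        df = pd.read_csv(path, dtype={"stage": str})
        tokens = [str(t).strip() for t in df["stage"]]
        lines = list(range(2, len(tokens) + 2))
    else:
        tokens, lines = [], []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens.append(line)
            lines.append(lineno)
    stages = []
    for token, lineno in zip(tokens, lines):
        if token not in dialect:
            raise ValueError(f"{path}:{lineno}: unmapped stage token {token!r}")
        stages.append(dialect[token])
    return Hypnogram(stages=np.asarray(stages, dtype="<U3"), epoch_len_s=epoch_len_s)


def write_hypnogram(
    hyp: Hypnogram,
    path: str | Path,
    probs: StageProbabilities | None = None,
) -> Path:
    """Write a hypnogram (and optional stage probabilities) as CSV.

    Columns: ``epoch_index, stage`` plus, when probabilities are supplied,
    ``p_W, p_N1, p_N2, p_N3, p_R, confidence``. :func:`read_hypnogram`
    inverts the stage column.
    """
    path = Path(path)
    if probs is not None and len(probs) != len(hyp):
        raise ValueError(
            f"probability rows ({len(probs)}) do not match epochs ({len(hyp)})"
        )
    df = pd.DataFrame({"epoch_index": np.arange(len(hyp)), "stage": hyp.stages})
    if probs is not None:
        for j, col in enumerate(_PROB_COLUMNS):
            df[col] = probs.probs[:, j]
        df["confidence"] = probs.confidence
    df.to_csv(path, index=False, float_format="%.6f")
    return path
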