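"""File I/O: delimited-text datasets with YAML sidecars and a WFDB reader.

Datasets are stored as plain text, one segment per row, next to a YAML
sidecar recording the sampling rate, the generator seed and a hash of the
producing configuration, so every artifact is traceable to the run that
made it.  An optional ``.npz`` copy of the same matrix is written for fast
reload.

``read_wfdb_segments`` is a minimal reader for PhysioNet-style records
(MIT header ``.hea`` plus ``.dat`` in format 212 or 16), enough to pull a
named lead and window it; it is never required by the synthetic pipeline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .preprocess import SignalSegment
from .synthetic_data import segment_signal


VALID_METHODS = ("deep", "gaussian+deep-decoder", "bernoulli+deep-decoder",
                 "omp", "sp")


@dataclass
class ExperimentConfig:
    """A full experiment description: data source, arms, and protocol.

    ``source`` is either a synthetic-generator spec mapping or a WFDB
    directory with record/lead lists; ``methods`` name the arms to run.
    Round-trips through YAML so runs are declaratively reproducible.
    """

    source: dict
    sensing_rates: list
    methods: list
    seed: int = 0
    epochs: int = 15
    batch_size: int = 32
    learning_rate: float = 5e-4
    noise_snrs: list = field(default_factory=list)
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.sensing_rates:
            raise ValueError("at least one sensing rate required")
        if not self.methods:
            raise ValueError("at least one method required")
        unknown = [m for m in self.methods if m not in VALID_METHODS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; choose from {VALID_METHODS}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_dataset(prefix, data: np.ndarray, sampling_rate: float, seed: int,
                  extra_meta: dict | None = None, binary: bool = False) -> Path:
    """Write an (n, N) dataset as ``<prefix>.txt`` (+ ``.yaml`` sidecar)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    txt = prefix.with_suffix(".txt")
    np.savetxt(txt, data, fmt="%.10g")
    meta = {
        "sampling_rate": float(sampling_rate),
        "seed": int(seed),
        "n_segments": int(data.shape[0]),
        "segment_length": int(data.shape[1]),
    }
    if extra_meta:
        meta.update(extra_meta)
    meta["config_hash"] = config_hash(meta)
    with open(prefix.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    if binary:
        np.savez(prefix.with_suffix(".npz"), data=data)
    return txt


def read_dataset(prefix) -> tuple[np.ndarray, dict]:
    """Read a dataset written by :func:`write_dataset` (npz preferred)."""
    prefix = Path(prefix)
    if prefix.suffix in (".txt", ".npz", ".yaml"):
        prefix = prefix.with_suffix("")
    meta_path = prefix.with_suffix(".yaml")
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    npz = prefix.with_suffix(".npz")
    if npz.exists():
        with np.load(npz) as data:
            return np.atleast_2d(data["data"]), meta
    txt = prefix.with_suffix(".txt")
    if not txt.exists():
        raise FileNotFoundError(f"no dataset at {prefix}(.txt|.npz)")
    return np.atleast_2d(np.loadtxt(txt)), meta


# ---------------------------------------------------------------------------
# WFDB (MIT-format) records
# ---------------------------------------------------------------------------

def _parse_header(path: Path):
    lines = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_tokens = lines[0].split()
    record = rec_tokens[0].split("/")[0]
    nsig = int(rec_tokens[1])
    fs = float(rec_tokens[2].split("/")[0]) if len(rec_tokens) > 2 else 250.0
    nsamp = int(rec_tokens[3]) if len(rec_tokens) > 3 else 0
    signals = []
    for ln in lines[1:1 + nsig]:
        tok = ln.split()
        fmt = tok[1].split("x")[0].split(":")[0].split("+")[0]
        gain_field = tok[2] if len(tok) > 2 else "200"
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            gain = float(gain_part[:gain_part.index("(")])
            baseline = int(gain_part[gain_part.index("(") + 1:gain_part.index(")")])
        else:
            gain = float(gain_part)
            baseline = int(tok[4]) if len(tok) > 4 else 0  # adc_zero fallback
        if gain == 0:
            gain = 200.0
        description = " ".join(tok[8:]) if len(tok) > 8 else f"sig{len(signals)}"
        signals.append({"file": tok[0], "format": int(fmt), "gain": gain,
                        "baseline": baseline, "description": description})
    return record, nsig, fs, nsamp, signals


def _read_dat(path: Path, fmt: int, nsig: int, nsamp: int) -> np.ndarray:
    raw = path.read_bytes()
    if fmt == 16:
        adc = np.frombuffer(raw, dtype="<i2")
        adc = adc[: (len(adc) // nsig) * nsig].reshape(-1, nsig)
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (len(b) // 3) * 3].reshape(-1, 3)
        s1 = ((b[:, 1].astype(np.int32) & 0x0F) << 8) | b[:, 0]
        s2 = ((b[:, 1].astype(np.int32) & 0xF0) << 4) | b[:, 2]
        s1 = np.where(s1 >= 2048, s1 - 4096, s1)
        s2 = np.where(s2 >= 2048, s2 - 4096, s2)
        flat = np.empty(2 * len(b), dtype=np.int32)
        flat[0::2], flat[1::2] = s1, s2
        adc = flat[: (len(flat) // nsig) * nsig].reshape(-1, nsig)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt} (supported: 16, 212)")
    if nsamp:
        adc = adc[:nsamp]
    return adc


def read_wfdb_record(directory, record_id: str):
    """Read a whole MIT-format record: (physical (nsamp, nsig), fs, lead names)."""
    directory = Path(directory)
    header = directory / f"{record_id}.hea"
    if not header.exists():
        raise FileNotFoundError(f"record {record_id!r}: missing header {header}")
    record, nsig, fs, nsamp, signals = _parse_header(header)
    fmts = {s["format"] for s in signals}
    files = {s["file"] for s in signals}
    if len(fmts) != 1 or len(files) != 1:
        raise ValueError(f"record {record_id!r}: mixed signal files/formats unsupported")
    adc = _read_dat(directory / signals[0]["file"], fmts.pop(), nsig, nsamp)
    phys = np.empty(adc.shape, dtype=float)
    for j, sig in enumerate(signals):
        phys[:, j] = (adc[:, j] - sig["baseline"]) / sig["gain"]
    return phys, fs, [s["description"] for s in signals]


def read_wfdb_segments(directory, record_ids, lead_name: str,
                       segment_length: int = 256, count: int = 10,
                       strategy: str = "even") -> list[SignalSegment]:
    """Extract windows of the named lead from MIT-format records.

    ``count`` segments are taken per record, evenly spaced by default.
    Raises naming the record when it or the lead is missing.
    """
    segments: list[SignalSegment] = []
    for rid in record_ids:
        phys, fs, leads = read_wfdb_record(directory, rid)
        if lead_name not in leads:
            raise ValueError(
                f"record {rid!r} has no lead {lead_name!r}; available: {leads}")
        channel = phys[:, leads.index(lead_name)]
        segs = segment_signal(channel, segment_length, count, strategy=strategy,
                              sampling_rate=fs, record_id=str(rid))
        segments.extend(segs)
    return segments


def write_wfdb_record(directory, record_id: str, signals: np.ndarray, fs: float,
                      lead_names, gain: float = 200.0, baseline: int = 0) -> None:
    """Write a format-16 MIT record (fixture/testing helper).

    Physical values are quantized to ``round(x * gain + baseline)`` int16
    ADC units, so a read-back round-trips within 1/(2*gain).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[0] < signals.shape[1]:
        raise ValueError("signals must be (nsamp, nsig) with nsamp >= nsig")
    nsamp, nsig = signals.shape
    if len(lead_names) != nsig:
        raise ValueError("one lead name per signal column required")
    adc = np.clip(np.round(signals * gain + baseline), -32768, 32767).astype("<i2")
    dat = f"{record_id}.dat"
    (directory / dat).write_bytes(adc.reshape(-1).tobytes())
    lines = [f"{record_id} {nsig} {fs:g} {nsamp}"]
    for j, name in enumerate(lead_names):
        first = int(adc[0, j])
        lines.append(f"{dat} 16 {gain:g}({baseline})/mV 16 {baseline} {first} 0 0 {name}")
    (directory / f"{record_id}.hea").write_text("\n".join(lines) + "\n")
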