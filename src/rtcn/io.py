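"""ECG record and heartbeat containers with WFDB and beat-dataset I/O.

Records are carried as :class:`EcgRecord` (multi-lead signal in millivolts plus
patient/label metadata) and segmented heartbeats as :class:`Beat` (fixed-length
windows anchored on the R peak).  WFDB support covers the header + format-16
signal layout used by the PhysioNet resting-ECG databases: enough to round-trip
the single-lead records this pipeline consumes.

Patient IDs ride along every container so the inter-patient split can guarantee
that no patient contributes beats to both partitions.
"""
from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

import numpy as np

#: The 12 diagnostic classes: 11 myocardial-infarction locations plus healthy control.
CLASSES = (
    "AMI", "ALMI", "ASMI", "ASLMI",
    "IMI", "ILMI", "IPMI", "IPLMI",
    "LMI", "PMI", "PLMI", "HC",
)

#: Default heartbeat window: samples before R, after R (window includes R itself).
PRE_SAMPLES = 250
POST_SAMPLES = 400
BEAT_LENGTH = PRE_SAMPLES + POST_SAMPLES + 1  # 651

UNKNOWN_LABEL = "unknown"


class LeadNotFoundError(KeyError):
    """Requested ECG lead is absent from a record."""


@dataclass
class EcgRecord:
    """A multi-lead ECG signal with metadata.

    Attributes
    ----------
    record_id, patient_id : str
        Record accession and the patient it belongs to.
    sampling_rate_hz : float
        Samples per second (> 0).
    leads : tuple of str
        Ordered lead names, one per signal column.
    signal : ndarray, shape (n_samples, n_leads)
        Amplitudes in millivolts.
    label : str
        One of :data:`CLASSES` or ``"unknown"``.
    """

    record_id: str
    patient_id: str
    sampling_rate_hz: float
    leads: tuple
    signal: np.ndarray
    label: str = UNKNOWN_LABEL

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape[0] == 1 and len(self.leads) == 1 and self.signal.shape[1] > 1:
            self.signal = self.signal.T
        self.leads = tuple(self.leads)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.signal.shape[0] < 1:
            raise ValueError("record must contain at least one sample")
        if self.signal.shape[1] != len(self.leads):
            raise ValueError(
                f"signal has {self.signal.shape[1]} columns but {len(self.leads)} lead names"
            )
        if self.label != UNKNOWN_LABEL and self.label not in CLASSES:
            raise ValueError(f"unknown class label {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    def lead(self, name: str) -> np.ndarray:
        """Return one lead as a 1-D array; raise LeadNotFoundError otherwise."""
        key = name.lower()
        lowered = [ld.lower() for ld in self.leads]
        if key not in lowered:
            raise LeadNotFoundError(
                f"lead {name!r} not present; available leads: {sorted(self.leads)}"
            )
        return self.signal[:, lowered.index(key)]

    def single_lead(self, name: str) -> "EcgRecord":
        """A copy of this record restricted to one lead."""
        sig = self.lead(name)[:, None]
        return replace(self, leads=(name,), signal=sig)


@dataclass
class Beat:
    """A fixed-length heartbeat window in millivolts, anchored on its R peak."""

    samples: np.ndarray
    label: str
    patient_id: str
    r_index: int = PRE_SAMPLES
    source: str = "real"  # "real" | "synthetic"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not 0 <= self.r_index < self.samples.size:
            raise ValueError("r_index outside the beat window")
        if self.label != UNKNOWN_LABEL and self.label not in CLASSES:
            raise ValueError(f"unknown class label {self.label!r}")
        if self.source not in ("real", "synthetic"):
            raise ValueError("source must be 'real' or 'synthetic'")

    def __len__(self):
        return self.samples.size


# ---------------------------------------------------------------------------
# WFDB (header + format-16 signal) read/write
# ---------------------------------------------------------------------------

def write_wfdb_record(record: EcgRecord, directory, adc_gain: float = 1000.0) -> str:
    """Write a record as a WFDB header/signal pair (format 16, interleaved int16).

    Amplitudes are quantised at ``adc_gain`` ADC units per millivolt.  Returns
    the record path (without extension).
    """
    os.makedirs(directory, exist_ok=True)
    base = os.path.join(directory, record.record_id)
    n, k = record.signal.shape
    counts = np.rint(record.signal * adc_gain)
    if np.abs(counts).max(initial=0) > 32767:
        raise ValueError("signal exceeds int16 range at this ADC gain")
    counts = counts.astype("<i2")
    with open(base + ".dat", "wb") as fh:
        fh.write(counts.reshape(-1).tobytes())  # row-major == sample-interleaved
    fs = record.sampling_rate_hz
    fs_txt = f"{fs:g}"
    lines = [f"{record.record_id} {k} {fs_txt} {n}"]
    for lead in record.leads:
        lines.append(f"{record.record_id}.dat 16 {adc_gain:g}(0)/mV 16 0 0 0 0 {lead}")
    lines.append(f"#patient_id: {record.patient_id}")
    lines.append(f"#label: {record.label}")
    with open(base + ".hea", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return base


def read_wfdb_record(path, lead: str | None = None) -> EcgRecord:
    """Read a WFDB record (header + single format-16 .dat file).

    Parameters
    ----------
    path : str
        Record path with or without the ``.hea`` extension.
    lead : str, optional
        If given, the returned record is restricted to this lead; a missing
        lead raises :class:`LeadNotFoundError` naming the available leads.
    """
    base = str(path)
    if base.endswith(".hea"):
        base = base[:-4]
    hea = base + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    with open(hea) as fh:
        raw = [ln.rstrip("\n") for ln in fh if ln.strip()]
    comments = [ln for ln in raw if ln.startswith("#")]
    body = [ln for ln in raw if not ln.startswith("#")]
    head = body[0].split()
    record_id, n_sig = head[0], int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    n_samples = int(head[3]) if len(head) > 3 else 0

    leads, gains, baselines, dat_files, fmts = [], [], [], [], []
    for ln in body[1 : 1 + n_sig]:
        toks = ln.split()
        dat_files.append(toks[0])
        fmts.append(toks[1].split("x")[0].split(":")[0].split("+")[0])
        gain_tok = toks[2] if len(toks) > 2 else "200"
        m = re.match(r"([-+0-9.eE]+)(?:\(([-+0-9]+)\))?(?:/.*)?$", gain_tok)
        gains.append(float(m.group(1)) if m and float(m.group(1)) != 0 else 200.0)
        baselines.append(int(m.group(2)) if m and m.group(2) else 0)
        leads.append(toks[-1])
    if len(set(dat_files)) != 1 or set(fmts) != {"16"}:
        raise ValueError("only single-file format-16 WFDB records are supported")

    with open(os.path.join(os.path.dirname(base) or ".", dat_files[0]), "rb") as fh:
        counts = np.frombuffer(fh.read(), dtype="<i2")
    counts = counts[: (counts.size // n_sig) * n_sig].reshape(-1, n_sig).astype(float)
    if n_samples:
        counts = counts[:n_samples]
    signal = (counts - np.asarray(baselines)) / np.asarray(gains)

    patient_id, label = record_id, UNKNOWN_LABEL
    for cm in comments:
        m = re.match(r"#\s*patient[_ ]?id:\s*(\S+)", cm, flags=re.I)
        if m:
            patient_id = m.group(1)
        m = re.match(r"#\s*label:\s*(\S+)", cm, flags=re.I)
        if m:
            label = m.group(1)

    rec = EcgRecord(record_id, patient_id, fs, tuple(leads), signal, label)
    return rec.single_lead(lead) if lead is not None else rec


# ---------------------------------------------------------------------------
# Beat dataset container (columnar: one samples table + one metadata table)
# ---------------------------------------------------------------------------

def save_beats(beats, path) -> str:
    """Persist a homogeneous beat list losslessly (float64 samples + metadata).

    The container is a single ``.npz`` holding the samples matrix and parallel
    metadata columns; :func:`load_beats` restores the list element-wise.
    """
    beats = list(beats)
    if not beats:
        raise ValueError("cannot save an empty beat list")
    lengths = {len(b) for b in beats}
    if len(lengths) != 1:
        raise ValueError(f"heterogeneous beat lengths: {sorted(lengths)}")
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    np.savez(
        path,
        samples=np.stack([b.samples for b in beats]),
        label=np.array([b.label for b in beats]),
        patient_id=np.array([b.patient_id for b in beats]),
        r_index=np.array([b.r_index for b in beats], dtype=np.int64),
        source=np.array([b.source for b in beats]),
    )
    return path


def load_beats(path):
    """Inverse of :func:`save_beats`."""
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    with np.load(path, allow_pickle=False) as z:
        return [
            Beat(z["samples"][i], str(z["label"][i]), str(z["patient_id"][i]),
                 int(z["r_index"][i]), str(z["source"][i]))
            for i in range(z["samples"].shape[0])
        ]


def class_counts(beats) -> dict:
    """Per-class beat counts (only classes that occur)."""
    out: dict = {}
    for b in beats:
        out[b.label] = out.get(b.label, 0) + 1
    return out
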