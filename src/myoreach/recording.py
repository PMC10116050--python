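"""Multichannel sEMG recording container and delimited-text I/O.

A recording is a dense [n_channels x n_samples] matrix in millivolts with a
fixed sampling rate and a role label per channel.  The forearm montage is the
antagonist wrist pair (flexor carpi ulnaris, extensor carpi ulnaris) plus four
intermediate electrodes; recordings from the DMD-like profile carry one extra
``trigger`` channel (gastrocnemius switch electrode).

On disk a recording is a CSV with header ``time_s,ch1,...,chN`` and a sidecar
JSON holding the sampling rate, channel roles and subject-profile id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

FOREARM_ROLES = ("fcu", "ecu", "mid1", "mid2", "mid3", "mid4")
TRIGGER_ROLE = "trigger"
VALID_ROLES = FOREARM_ROLES + (TRIGGER_ROLE,)


@dataclass
class EmgRecording:
    """Raw multichannel sEMG.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in millivolts.
    fs : float
        Sampling rate in Hz (1000 Hz for protocol-conformant runs).
    channel_roles : tuple of str
        One role per channel, drawn from ``fcu | ecu | mid1..mid4 | trigger``.
    subject_profile_id : str
        Free-text identifier of the generating subject profile.
    """

    samples: np.ndarray
    fs: float
    channel_roles: tuple[str, ...]
    subject_profile_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_roles = tuple(self.channel_roles)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D [n_channels x n_samples] array")
        if len(self.channel_roles) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_roles)} roles for {self.samples.shape[0]} channels"
            )
        unknown = set(self.channel_roles) - set(VALID_ROLES)
        if unknown:
            raise ValueError(f"unknown channel roles: {sorted(unknown)}")
        for role in ("fcu", "ecu"):
            if self.channel_roles.count(role) != 1:
                raise ValueError(f"exactly one '{role}' channel required")
        if self.channel_roles.count(TRIGGER_ROLE) > 1:
            raise ValueError("at most one trigger channel allowed")
        if self.fs <= 40:
            raise ValueError("sampling rate must exceed 40 Hz (2x high-pass cutoff)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def has_trigger(self) -> bool:
        return TRIGGER_ROLE in self.channel_roles

    def channel(self, role: str) -> np.ndarray:
        """Return the samples of the channel with the given role."""
        return self.samples[self.channel_index(role)]

    def channel_index(self, role: str) -> int:
        try:
            return self.channel_roles.index(role)
        except ValueError:
            raise KeyError(f"no channel with role '{role}'") from None

    @property
    def forearm_indices(self) -> np.ndarray:
        """Indices of the six forearm channels, trigger excluded."""
        return np.array(
            [i for i, r in enumerate(self.channel_roles) if r != TRIGGER_ROLE]
        )

    def replace_samples(self, samples: np.ndarray) -> "EmgRecording":
        return EmgRecording(samples, self.fs, self.channel_roles, self.subject_profile_id)

    # ---------------------------------------------------------------- I/O

    def save(self, csv_path: str | Path) -> None:
        """Write the recording CSV plus a ``<stem>.meta.json`` sidecar."""
        csv_path = Path(csv_path)
        t = np.arange(self.n_samples) / self.fs
        cols = {"time_s": t}
        for i in range(self.n_channels):
            cols[f"ch{i + 1}"] = self.samples[i]
        pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.6g")
        meta = {
            "fs": self.fs,
            "channel_roles": list(self.channel_roles),
            "subject_profile_id": self.subject_profile_id,
        }
        _sidecar_path(csv_path).write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, csv_path: str | Path) -> "EmgRecording":
        """Read a recording CSV + sidecar, validating the time column."""
        csv_path = Path(csv_path)
        meta = json.loads(_sidecar_path(csv_path).read_text())
        df = pd.read_csv(csv_path)
        if "time_s" not in df.columns:
            raise ValueError("recording CSV must have a 'time_s' column")
        fs = float(meta["fs"])
        t = df["time_s"].to_numpy()
        expected = np.arange(len(t)) / fs
        if not np.allclose(t, expected, atol=0.51 / fs):
            raise ValueError("time_s column is not monotone at 1/fs spacing")
        samples = df.drop(columns="time_s").to_numpy().T
        return cls(
            samples=samples,
            fs=fs,
            channel_roles=tuple(meta["channel_roles"]),
            subject_profile_id=meta.get("subject_profile_id", ""),
        )


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix("").with_suffix(".meta.json")
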