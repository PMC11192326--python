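"""In-memory containers for continuous recordings, epochs and rejection books.

Voltages are in microvolts throughout. Trial metadata travels as a pandas
DataFrame so that the preprocessing chain can annotate trials without
touching the voltage arrays.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: trigger-table columns, one row per stimulus presentation
TRIGGER_COLUMNS = ["sample", "category", "location", "dot_change"]


@dataclass
class ContinuousRecording:
    """Multichannel continuous EEG series for one participant.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage in microvolts.
    sampling_rate : float
        Hz.
    channel_names : list of str
        Scalp channels first, then any auxiliary channels (reference,
        EOG derivations).
    triggers : pandas.DataFrame
        Columns ``sample`` (int, strictly increasing), ``category``,
        ``location``, ``dot_change``.
    participant : int
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    triggers: pd.DataFrame
    participant: int = 0

    def __post_init__(self):
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length mismatch")
        s = np.asarray(self.triggers["sample"])
        if len(s) and (np.any(np.diff(s) <= 0) or s[-1] >= self.data.shape[1] or s[0] < 0):
            raise ValueError("trigger samples must be strictly increasing and in range")

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            data=self.data.copy(),
            sampling_rate=self.sampling_rate,
            channel_names=list(self.channel_names),
            triggers=self.triggers.copy(),
            participant=self.participant,
        )

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None


@dataclass
class EpochSet:
    """Epoched voltage data: trials x channels x samples.

    ``times`` holds the nominal epoch time axis in ms relative to stimulus
    onset; metadata has one row per trial with at least ``participant``,
    ``category``, ``location``, ``dot_change`` and ``kept`` columns.
    """

    data: np.ndarray
    times: np.ndarray
    channel_names: list[str]
    metadata: pd.DataFrame
    sampling_rate: float

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[0] != len(self.metadata):
            raise ValueError("metadata length must equal trial count")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length mismatch")
        if self.data.shape[2] != len(self.times):
            raise ValueError("times length mismatch")
        if "kept" not in self.metadata.columns:
            self.metadata = self.metadata.assign(kept=True)
        self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def scalp_indices(self, scalp_names: list[str]) -> np.ndarray:
        return np.array([self.channel_names.index(n) for n in scalp_names])

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times=self.times.copy(),
            channel_names=list(self.channel_names),
            metadata=self.metadata.copy(),
            sampling_rate=self.sampling_rate,
        )

    def save(self, directory) -> None:
        """Write the container: .npy voltages + JSON sidecar + TSV metadata."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "epochs.npy", self.data)
        self.metadata.to_csv(d / "metadata.tsv", sep="\t", index=False)
        with open(d / "sidecar.json", "w") as fh:
            json.dump(
                {
                    "sampling_rate": self.sampling_rate,
                    "times_ms": self.times.tolist(),
                    "channel_names": self.channel_names,
                },
                fh,
            )

    @classmethod
    def load(cls, directory) -> "EpochSet":
        d = Path(directory)
        with open(d / "sidecar.json") as fh:
            side = json.load(fh)
        return cls(
            data=np.load(d / "epochs.npy"),
            times=np.asarray(side["times_ms"], dtype=float),
            channel_names=list(side["channel_names"]),
            metadata=pd.read_csv(d / "metadata.tsv", sep="\t"),
            sampling_rate=float(side["sampling_rate"]),
        )


FLAG_COLUMNS = ("dot_task", "abs_threshold", "global_sd")


@dataclass
class RejectionReport:
    """Per-trial rejection flags and per-participant kept-trial counts.

    A trial is kept iff all flags are False. Flags accumulate: each
    preprocessing stage ORs its own column in.
    """

    flags: pd.DataFrame  # boolean columns FLAG_COLUMNS, aligned with trials

    @classmethod
    def empty(cls, metadata: pd.DataFrame) -> "RejectionReport":
        flags = pd.DataFrame(
            {c: np.zeros(len(metadata), dtype=bool) for c in FLAG_COLUMNS}
        )
        for c in ("participant", "category", "location"):
            if c in metadata.columns:
                flags[c] = metadata[c].to_numpy()
        return cls(flags=flags.reset_index(drop=True))

    @property
    def kept(self) -> np.ndarray:
        return ~self.flags[list(FLAG_COLUMNS)].any(axis=1).to_numpy()

    def apply(self, es: EpochSet) -> EpochSet:
        """Write the kept column back into the EpochSet metadata."""
        es.metadata["kept"] = self.kept
        return es

    def kept_counts(self) -> pd.DataFrame:
        """Kept-trial counts per participant x condition (category, location)."""
        df = self.flags.copy()
        df["kept"] = self.kept
        return (
            df.groupby(["participant", "category", "location"], observed=True)["kept"]
            .sum()
            .reset_index(name="n_kept")
        )

    def to_tsv(self, path) -> None:
        self.flags.assign(kept=self.kept).to_csv(path, sep="\t", index=False)
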