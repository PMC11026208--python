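"""The EEG epoch container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 9-channel neonatal 10-20 montage used throughout.
NEONATAL_CHANNELS = ("Fp1", "Fp2", "C3", "C4", "T3", "T4", "O1", "O2", "Cz")


@dataclass
class EEGEpoch:
    """A contiguous multichannel EEG segment, the unit of analysis.

    Parameters
    ----------
    data
        Channels x samples voltage matrix in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        Ordered channel labels, one per row of ``data``.
    reference
        ``"native"`` (as recorded) or ``"common_average"`` (each
        time-sample has zero mean across channels).
    sleep_state
        Optional sleep-state tag, ``"QS"`` or ``"NQS"``.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = NEONATAL_CHANNELS
    reference: str = "native"
    sleep_state: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch contains non-finite values")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.reference not in ("native", "common_average"):
            raise ValueError(f"unknown reference {self.reference!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def is_average_referenced(self, rtol: float = 1e-9) -> bool:
        """Check the per-sample channel means are ~0 relative to the signal."""
        means = self.data.mean(axis=0)
        scale = max(np.abs(self.data).max(), np.finfo(float).tiny)
        return bool(np.all(np.abs(means) <= rtol * scale))

    def copy_with(self, **changes) -> "EEGEpoch":
        if "data" not in changes:
            changes["data"] = self.data.copy()
        return replace(self, **changes)
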