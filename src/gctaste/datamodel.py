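"""Core containers and binning utilities for trial-structured ensemble recordings.

A recording session is represented as an :class:`EnsembleDataset`: a binary
spike raster (trials x units x 1-ms bins, spanning -2000..+2500 ms around
stimulus delivery), a trial table (taste label, laser condition), and a unit
table (spike half-width, session id).  All downstream analyses consume this
container.  Sessions are serialized to a single HDF5 file; the trial and unit
tables can additionally be exported as CSV for inspection.

Time convention: all times are in ms relative to stimulus delivery; windows
are half-open ``[t0, t1)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

#: Canonical taste labels, in fixed order (used for tie-breaking in decoders).
TASTES = ("Sucrose", "NaCl", "Acid", "QHCl")

#: Hedonic rank of each tastant (higher = more palatable):
#: Sucrose > NaCl > Citric Acid > Quinine-HCl.
PALATABILITY_RANKS = {"Sucrose": 4, "NaCl": 3, "Acid": 2, "QHCl": 1}

T_START_MS = -2000
T_STOP_MS = 2500

_FORMAT_VERSION = "1"


class FormatError(ValueError):
    """A session file is missing a required group, dataset, or column."""


class ConsistencyError(ValueError):
    """Components of a dataset disagree (e.g. trial counts)."""


def palatability_map() -> dict[str, int]:
    """Return the taste -> hedonic rank mapping (a permutation of 1..4)."""
    return dict(PALATABILITY_RANKS)


def _normalize_condition(condition) -> bool:
    """Map 'Off'/'On' (case-insensitive) or bool to a laser_on bool."""
    if isinstance(condition, (bool, np.bool_)):
        return bool(condition)
    c = str(condition).strip().lower()
    if c in ("off", "laser-off", "control", "0", "false"):
        return False
    if c in ("on", "laser-on", "perturbed", "1", "true"):
        return True
    raise ValueError(f"unrecognized laser condition: {condition!r}")


@dataclass
class Psth:
    """Trial-averaged firing rate (Hz) on a moving window.

    ``rates[k]`` is the mean spike count in window ``[t0 + k*step, t0 +
    k*step + window)`` across trials, converted to Hz.
    """

    rates: np.ndarray
    time_centers_ms: np.ndarray
    window_ms: float
    step_ms: float

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.time_centers_ms = np.asarray(self.time_centers_ms, dtype=float)
        if self.rates.shape[-1] != self.time_centers_ms.shape[0]:
            raise ConsistencyError("rates and time centers disagree in length")
        if np.any(self.rates < 0):
            raise ValueError("firing rates must be non-negative")


@dataclass
class EnsembleDataset:
    """One recording session: rasters + trial table + unit table.

    Attributes
    ----------
    rasters : uint8 array, shape (n_trials, n_units, n_bins)
        Binary spike indicators in 1-ms bins over ``[t_start_ms, t_start_ms
        + n_bins)``.
    trial_table : DataFrame with columns ``trial_index``, ``taste``,
        ``laser_on`` (bool).
    unit_table : DataFrame with columns ``unit_id``, ``half_width_ms``,
        ``session_id``.
    """

    rasters: np.ndarray
    trial_table: pd.DataFrame
    unit_table: pd.DataFrame
    bin_size_ms: int = 1
    t_start_ms: int = T_START_MS

    def __post_init__(self):
        self.rasters = np.asarray(self.rasters)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.rasters.ndim != 3:
            raise ConsistencyError("rasters must be trials x units x time")
        n_trials, n_units, _ = self.rasters.shape
        if n_units < 1:
            raise ConsistencyError("dataset must contain at least one unit")
        for col in ("trial_index", "taste", "laser_on"):
            if col not in self.trial_table.columns:
                raise FormatError(f"trial_table missing column {col!r}")
        for col in ("unit_id", "half_width_ms", "session_id"):
            if col not in self.unit_table.columns:
                raise FormatError(f"unit_table missing column {col!r}")
        if len(self.trial_table) != n_trials:
            raise ConsistencyError(
                f"trial_table has {len(self.trial_table)} rows for "
                f"{n_trials} raster trials"
            )
        if len(self.unit_table) != n_units:
            raise ConsistencyError(
                f"unit_table has {len(self.unit_table)} rows for "
                f"{n_units} raster units"
            )
        unknown = set(self.trial_table["taste"]) - set(TASTES)
        if unknown:
            raise ConsistencyError(f"unknown taste labels: {sorted(unknown)}")
        vals = np.unique(self.rasters)
        if not np.all(np.isin(vals, (0, 1))):
            raise ConsistencyError("raster entries must be binary")

    # -- basic geometry --------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.rasters.shape[0]

    @property
    def n_units(self) -> int:
        return self.rasters.shape[1]

    @property
    def n_bins(self) -> int:
        return self.rasters.shape[2]

    def time_index(self, t_ms: float) -> int:
        """Index of the 1-ms bin containing time ``t_ms``."""
        idx = int(round((t_ms - self.t_start_ms) / self.bin_size_ms))
        if not 0 <= idx <= self.n_bins:
            raise ValueError(f"time {t_ms} ms outside the recorded range")
        return idx

    def trial_mask(self, taste: str | None = None, laser=None) -> np.ndarray:
        """Boolean mask over trials, filtered by taste and/or laser condition."""
        mask = np.ones(self.n_trials, dtype=bool)
        if taste is not None:
            mask &= (self.trial_table["taste"] == taste).to_numpy()
        if laser is not None:
            mask &= (
                self.trial_table["laser_on"].to_numpy(dtype=bool)
                == _normalize_condition(laser)
            )
        return mask

    def bin_counts(
        self,
        window_ms: tuple[float, float],
        bin_ms: int,
        trials: np.ndarray | None = None,
        units: np.ndarray | None = None,
    ) -> np.ndarray:
        """Spike counts in consecutive ``bin_ms`` bins over ``window_ms``.

        Returns an int array of shape (n_selected_trials, n_units, n_bins);
        only whole bins fitting inside the window are returned.
        """
        i0 = self.time_index(window_ms[0])
        n_out = int((window_ms[1] - window_ms[0]) // bin_ms)
        r = self.rasters
        if trials is not None:
            r = r[trials]
        if units is not None:
            r = r[:, units]
        seg = r[:, :, i0 : i0 + n_out * bin_ms]
        return seg.reshape(seg.shape[0], seg.shape[1], n_out, bin_ms).sum(axis=3)


def compute_psth(
    rasters: np.ndarray,
    window_ms: float,
    step_ms: float,
    bin_size_ms: int = 1,
    t_start_ms: float = 0.0,
) -> Psth:
    """Moving-window trial-averaged firing rate for a trials x time raster.

    rate(Hz) = (mean spike count across trials in the window) / (window in s).
    Windows are half-open ``[t, t + window)`` and advance by ``step_ms``.
    """
    rasters = np.asarray(rasters, dtype=float)
    if rasters.ndim != 2:
        raise ValueError("compute_psth expects a trials x time array")
    if rasters.shape[0] == 0:
        raise ValueError("empty trial selection")
    if window_ms < bin_size_ms:
        raise ValueError("window must be at least one raster bin")
    if step_ms < 1:
        raise ValueError("step must be at least 1 ms")
    w = int(window_ms // bin_size_ms)
    s = int(step_ms // bin_size_ms)
    n_time = rasters.shape[1]
    n_windows = (n_time - w) // s + 1
    if n_windows < 1:
        raise ValueError("window longer than raster extent")
    mean_train = rasters.mean(axis=0)
    csum = np.concatenate([[0.0], np.cumsum(mean_train)])
    starts = np.arange(n_windows) * s
    counts = csum[starts + w] - csum[starts]
    rates = counts / (window_ms / 1000.0)
    centers = t_start_ms + starts * bin_size_ms + window_ms / 2.0
    return Psth(rates=rates, time_centers_ms=centers, window_ms=window_ms, step_ms=step_ms)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_dataset(dataset: EnsembleDataset, path) -> None:
    """Write a session to one HDF5 file (deterministic bytes for fixed input).

    Layout: ``/rasters`` (uint8, gzip), ``/trial_table/{trial_index,taste,
    laser_on}``, ``/unit_table/{unit_id,half_width_ms,session_id}``; bin size,
    time origin and format version stored as root attributes.
    """
    dataset.validate()
    opts = dict(track_times=False)
    with h5py.File(path, "w", libver="earliest") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["bin_size_ms"] = dataset.bin_size_ms
        f.attrs["t_start_ms"] = dataset.t_start_ms
        f.create_dataset(
            "rasters",
            data=dataset.rasters.astype(np.uint8),
            compression="gzip",
            compression_opts=4,
            shuffle=True,
            **opts,
        )
        tt = f.create_group("trial_table")
        tt.create_dataset(
            "trial_index",
            data=dataset.trial_table["trial_index"].to_numpy(dtype=np.int64),
            **opts,
        )
        tt.create_dataset(
            "taste",
            data=np.array(
                [t.encode() for t in dataset.trial_table["taste"]], dtype="S16"
            ),
            **opts,
        )
        tt.create_dataset(
            "laser_on",
            data=dataset.trial_table["laser_on"].to_numpy(dtype=np.uint8),
            **opts,
        )
        ut = f.create_group("unit_table")
        ut.create_dataset(
            "unit_id",
            data=np.array(
                [str(u).encode() for u in dataset.unit_table["unit_id"]], dtype="S32"
            ),
            **opts,
        )
        ut.create_dataset(
            "half_width_ms",
            data=dataset.unit_table["half_width_ms"].to_numpy(dtype=np.float64),
            **opts,
        )
        ut.create_dataset(
            "session_id",
            data=np.array(
                [str(s).encode() for s in dataset.unit_table["session_id"]],
                dtype="S32",
            ),
            **opts,
        )


def read_dataset(path) -> EnsembleDataset:
    """Read a session container written by :func:`write_dataset`."""
    with h5py.File(path, "r") as f:
        if "rasters" not in f:
            raise FormatError("file missing /rasters")
        for grp, cols in (
            ("trial_table", ("trial_index", "taste", "laser_on")),
            ("unit_table", ("unit_id", "half_width_ms", "session_id")),
        ):
            if grp not in f:
                raise FormatError(f"file missing /{grp}")
            for col in cols:
                if col not in f[grp]:
                    raise FormatError(f"file missing /{grp}/{col}")
        rasters = f["rasters"][()]
        trial_table = pd.DataFrame(
            {
                "trial_index": f["trial_table/trial_index"][()],
                "taste": [b.decode() for b in f["trial_table/taste"][()]],
                "laser_on": f["trial_table/laser_on"][()].astype(bool),
            }
        )
        unit_table = pd.DataFrame(
            {
                "unit_id": [b.decode() for b in f["unit_table/unit_id"][()]],
                "half_width_ms": f["unit_table/half_width_ms"][()],
                "session_id": [b.decode() for b in f["unit_table/session_id"][()]],
            }
        )
        bin_size_ms = int(f.attrs["bin_size_ms"])
        t_start_ms = int(f.attrs["t_start_ms"])
    return EnsembleDataset(
        rasters=rasters,
        trial_table=trial_table,
        unit_table=unit_table,
        bin_size_ms=bin_size_ms,
        t_start_ms=t_start_ms,
    )


def export_tables_csv(dataset: EnsembleDataset, trial_csv, unit_csv) -> None:
    """Export the trial and unit tables as UTF-8, comma-separated CSV."""
    dataset.trial_table.to_csv(trial_csv, index=False)
    dataset.unit_table.to_csv(unit_csv, index=False)
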