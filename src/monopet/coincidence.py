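"""Singles-to-coincidence processing.

Order of operations follows the acquisition electronics: per-module
paralysable dead time is applied to every crystal interaction (the detector
is busy regardless of the deposited energy), then the energy window, then
window-based pairing, and finally ground-truth classification into trues,
scatters and randoms using the decay lineage the simulator preserves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .mc import SinglesList

TRUE, SCATTER, RANDOM = 0, 1, 2
LABELS = {TRUE: "true", SCATTER: "scatter", RANDOM: "random"}


@dataclass
class CoincidenceList:
    """Columnar prompt-coincidence list with ground-truth labels."""

    module: np.ndarray  # (N, 2) int32
    position: np.ndarray  # (N, 2, 3) endpoint interaction points
    energy: np.ndarray  # (N, 2) float32 measured keV
    time: np.ndarray  # (N, 2) float64 ns
    decay_id: np.ndarray  # (N, 2) int64
    n_scatters: np.ndarray  # (N, 2) int16
    label: np.ndarray  # (N,) int8, TRUE/SCATTER/RANDOM

    def __len__(self) -> int:
        return len(self.label)

    @property
    def time_difference(self) -> np.ndarray:
        return self.time[:, 0] - self.time[:, 1]

    def select(self, mask: np.ndarray) -> "CoincidenceList":
        return CoincidenceList(
            self.module[mask],
            self.position[mask],
            self.energy[mask],
            self.time[mask],
            self.decay_id[mask],
            self.n_scatters[mask],
            self.label[mask],
        )

    def counts_by_class(self) -> Dict[str, int]:
        return {
            name: int((self.label == code).sum()) for code, name in LABELS.items()
        }

    @staticmethod
    def concatenate(parts: list["CoincidenceList"]) -> "CoincidenceList":
        fields = (
            "module",
            "position",
            "energy",
            "time",
            "decay_id",
            "n_scatters",
            "label",
        )
        return CoincidenceList(
            *(np.concatenate([getattr(p, f) for p in parts]) for f in fields)
        )


def apply_dead_time(
    singles: SinglesList, tau_ns: float, model: str = "paralysable"
) -> SinglesList:
    """Per-module paralysable dead time.

    An interaction is recorded iff no prior interaction on the same module
    occurred within ``tau`` before it; every arrival (recorded or not)
    extends the dead period, which for a time-ordered stream reduces to the
    gap-to-previous-arrival rule.
    """
    if model != "paralysable":
        raise ValueError("only the paralysable model is implemented")
    if len(singles) == 0:
        return singles
    t = singles.time
    if np.any(np.diff(t) < 0):
        raise ValueError("singles must be time-ordered")
    order = np.lexsort((t, singles.module))
    ts = t[order]
    ms = singles.module[order]
    gap_ok = np.empty(len(ts), dtype=bool)
    gap_ok[0] = True
    gap_ok[1:] = (ts[1:] - ts[:-1] > tau_ns) | (ms[1:] != ms[:-1])
    keep = np.zeros(len(ts), dtype=bool)
    keep[order] = gap_ok
    return singles.select(keep)


def energy_window_filter(
    singles: SinglesList, window: Tuple[float, float]
) -> SinglesList:
    """Keep singles with measured energy inside the closed window."""
    lo, hi = window
    return singles.select((singles.energy >= lo) & (singles.energy <= hi))


def pair_coincidences(
    singles: SinglesList,
    window_ns: float,
    policy: str = "killAll",
) -> CoincidenceList:
    """Window-based pairing of the filtered, time-ordered singles stream.

    Singles are clustered by chaining: a gap larger than the window closes
    the cluster.  A cluster of exactly two singles on distinct modules
    yields one prompt; larger clusters (multiples) are discarded under
    ``killAll`` or decomposed into all distinct-module pairs under
    ``takeAllGoods``.
    """
    if policy not in ("killAll", "takeAllGoods"):
        raise ValueError(f"unknown multiples policy {policy!r}")
    n = len(singles)
    empty = CoincidenceList(
        np.empty((0, 2), np.int32),
        np.empty((0, 2, 3)),
        np.empty((0, 2), np.float32),
        np.empty((0, 2)),
        np.empty((0, 2), np.int64),
        np.empty((0, 2), np.int16),
        np.empty(0, np.int8),
    )
    if n < 2:
        return empty
    t = singles.time
    if np.any(np.diff(t) < 0):
        raise ValueError("singles must be time-ordered")
    new_cluster = np.empty(n, dtype=bool)
    new_cluster[0] = True
    new_cluster[1:] = np.diff(t) > window_ns
    starts = np.flatnonzero(new_cluster)
    sizes = np.diff(np.append(starts, n))
    pair_first = starts[sizes == 2]
    idx1 = pair_first
    idx2 = pair_first + 1
    good = singles.module[idx1] != singles.module[idx2]
    idx1, idx2 = idx1[good], idx2[good]
    if policy == "takeAllGoods":
        extra1, extra2 = [], []
        multi = sizes > 2
        for size in np.unique(sizes[multi]):
            firsts = starts[sizes == size]
            members = firsts[:, None] + np.arange(size)[None, :]
            for a in range(size):
                for b in range(a + 1, size):
                    i = members[:, a]
                    j = members[:, b]
                    ok = (t[j] - t[i] <= window_ns) & (
                        singles.module[i] != singles.module[j]
                    )
                    extra1.append(i[ok])
                    extra2.append(j[ok])
        if extra1:
            idx1 = np.concatenate([idx1] + extra1)
            idx2 = np.concatenate([idx2] + extra2)
            order = np.argsort(t[idx1], kind="stable")
            idx1, idx2 = idx1[order], idx2[order]
    if len(idx1) == 0:
        return empty
    stack = lambda f: np.stack([getattr(singles, f)[idx1], getattr(singles, f)[idx2]], axis=1)
    coinc = CoincidenceList(
        stack("module").astype(np.int32),
        np.stack([singles.position[idx1], singles.position[idx2]], axis=1),
        stack("energy").astype(np.float32),
        stack("time"),
        stack("decay_id").astype(np.int64),
        stack("n_scatters").astype(np.int16),
        np.zeros(len(idx1), np.int8),
    )
    return classify_truth(coinc)


def classify_truth(coinc: CoincidenceList) -> CoincidenceList:
    """Label prompts: same decay and no phantom scatter -> true; same decay
    with any scattered photon -> scatter; different decays -> random."""
    same = coinc.decay_id[:, 0] == coinc.decay_id[:, 1]
    scattered = coinc.n_scatters.sum(axis=1) > 0
    label = np.where(same, np.where(scattered, SCATTER, TRUE), RANDOM)
    coinc.label = label.astype(np.int8)
    return coinc


def process_singles(
    singles: SinglesList,
    config,
    policy: str = "takeAllGoods",
    dead_time_order: str = "after_window",
) -> CoincidenceList:
    """Full chain: energy window / dead time -> pairing -> truth labels.

    ``dead_time_order`` selects whether the paralysable dead time acts on
    energy-qualified singles (``"after_window"``, the usual digitizer-chain
    placement and the default) or on every crystal interaction
    (``"before_window"``).
    """
    s = singles
    if dead_time_order == "before_window":
        s = apply_dead_time(s, config.dead_time, config.dead_time_model)
        s = energy_window_filter(s, config.energy_window)
    elif dead_time_order == "after_window":
        s = energy_window_filter(s, config.energy_window)
        s = apply_dead_time(s, config.dead_time, config.dead_time_model)
    else:
        raise ValueError(f"unknown dead_time_order {dead_time_order!r}")
    return pair_coincidences(s, config.coincidence_window, policy)
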