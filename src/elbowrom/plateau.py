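"""Hold-phase (plateau) detection in flexion-angle time series.

During a trial the examiner pauses for roughly three seconds at each
target angle; each pause shows up as a low-variance run in the angle
series. Plateaus are found with a rolling-window standard-deviation
detector, summarized by their mean angle, and optionally matched to the
nominal target angles of the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .kinematics import AngleSeries
from .rigid import ValidationError

__all__ = [
    "Plateau",
    "detect_plateaus",
    "match_to_nominal",
    "summarize_by_nominal",
]

DEFAULT_NOMINALS = (0.0, 45.0, 90.0, 135.0)


@dataclass(frozen=True)
class Plateau:
    """One detected hold: time span, angle statistics, optional nominal."""

    t_start: float
    t_end: float
    mean_deg: float
    sd_deg: float
    n_samples: int
    nominal_deg: float | None = None


def detect_plateaus(
    series: AngleSeries,
    window_s: float = 0.5,
    sd_threshold_deg: float = 1.5,
    min_duration_s: float = 2.0,
) -> list[Plateau]:
    """Find held phases as runs where the rolling SD stays below threshold.

    A centered rolling window of ``window_s`` seconds classifies each
    sample as quiet (SD ≤ ``sd_threshold_deg``) or moving; maximal quiet
    runs lasting at least ``min_duration_s`` become plateaus, each
    summarized by the mean and sample SD of its angles.
    """
    n = len(series)
    if n == 0:
        raise ValidationError("cannot detect plateaus in an empty series")
    dt = float(np.median(np.diff(series.t))) if n > 1 else 1.0
    win = max(2, int(round(window_s / dt)))
    if win > n:
        raise ValidationError(
            f"rolling window ({win} samples) longer than series ({n} samples)"
        )
    sd = pd.Series(series.phi).rolling(win, center=True, min_periods=win).std(ddof=1)
    quiet = (sd <= sd_threshold_deg).to_numpy(dtype=bool)

    plateaus: list[Plateau] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], quiet, [False]))))
    for start, stop in edges.reshape(-1, 2):  # stop is exclusive
        t0, t1 = series.t[start], series.t[stop - 1]
        if t1 - t0 < min_duration_s:
            continue
        phi = series.phi[start:stop]
        plateaus.append(
            Plateau(
                t_start=float(t0),
                t_end=float(t1),
                mean_deg=float(phi.mean()),
                sd_deg=float(phi.std(ddof=1)) if phi.size > 1 else 0.0,
                n_samples=int(phi.size),
            )
        )
    return plateaus


def match_to_nominal(
    plateaus: Sequence[Plateau],
    nominal: Sequence[float] = DEFAULT_NOMINALS,
    tol_deg: float = 10.0,
) -> list[Plateau]:
    """Assign each plateau to its nearest nominal target angle.

    A plateau is matched only if the nearest nominal lies within
    ``tol_deg``; when several plateaus claim the same nominal the closest
    wins (ties broken by earlier start), the rest stay unmatched. Returns
    new :class:`Plateau` objects in the original order.
    """
    nominal = [float(v) for v in nominal]
    if len(set(nominal)) != len(nominal):
        raise ValidationError("nominal angles must be distinct")

    claims: dict[float, list[tuple[float, float, int]]] = {}
    for i, p in enumerate(plateaus):
        if not nominal:
            continue
        nearest = min(nominal, key=lambda v: abs(p.mean_deg - v))
        if abs(p.mean_deg - nearest) <= tol_deg:
            claims.setdefault(nearest, []).append((abs(p.mean_deg - nearest), p.t_start, i))

    winner: dict[int, float] = {}
    for nom, cands in claims.items():
        cands.sort()  # by |delta|, then earlier start
        winner[cands[0][2]] = nom
    return [replace(p, nominal_deg=winner.get(i)) for i, p in enumerate(plateaus)]


def summarize_by_nominal(trials: Sequence[Sequence[Plateau]]) -> pd.DataFrame:
    """Per-nominal mean and sample SD of plateau means across trials.

    Only matched plateaus contribute; nominals with no matches anywhere
    are simply absent from the table (missing, not zero). Columns:
    ``mean_deg``, ``sd_deg``, ``n``; index: ``nominal_deg``.
    """
    rows = [
        {"nominal_deg": p.nominal_deg, "measured_deg": p.mean_deg}
        for trial in trials
        for p in trial
        if p.nominal_deg is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["mean_deg", "sd_deg", "n"]).rename_axis("nominal_deg")
    df = pd.DataFrame(rows)
    out = df.groupby("nominal_deg")["measured_deg"].agg(
        mean_deg="mean", sd_deg=lambda s: s.std(ddof=1), n="count"
    )
    out["n"] = out["n"].astype(int)
    return out
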