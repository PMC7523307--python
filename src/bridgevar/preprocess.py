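"""Preprocessing: reverse coding, lattice alignment, descriptives, screens.

The model downstream assumes equally spaced series; real prompts are
unequally spaced (jitter, nights, missed beeps).  ``align_to_grid`` places
each person's answered records on a ``delta_min`` lattice, inserting
explicit missing cells, so lagged coefficients refer to a fixed interval.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.tools.sm_exceptions import InterpolationWarning
from statsmodels.tsa.stattools import kpss as _sm_kpss

from .catalog import ItemCatalog
from .panel import EmaPanel, GriddedPanel, PersonGrid

logger = logging.getLogger(__name__)

__all__ = [
    "reverse_code",
    "align_to_grid",
    "GridAligner",
    "descriptives",
    "kpss_screen",
    "collinearity_check",
]


def reverse_code(panel: EmaPanel) -> EmaPanel:
    """Flip reverse-coded items (``score <- 8 - score``) and toggle the
    panel's ``coded`` flag.  Applying it twice restores the raw scores.

    Raises if declared-Likert scores fall outside the 1-7 range.
    """
    data = panel.data.copy()
    codes = panel.catalog.reverse_coded_codes
    vals = data[panel.catalog.codes]
    if panel.likert:
        answered = data["answered"].astype(bool)
        v = vals[answered]
        if ((v < 1) | (v > 7)).any().any():
            raise ValueError("Likert panel contains scores outside [1, 7]")
    data[codes] = 8.0 - data[codes]
    return EmaPanel(data=data, catalog=panel.catalog, metadata=panel.metadata,
                    coded=not panel.coded, likert=panel.likert)


def align_to_grid(panel: EmaPanel, delta_min: float = 180.0) -> GriddedPanel:
    """Place each person's answered records on an equally spaced lattice.

    The person-local origin is their first answered prompt; record at time
    ``t`` goes to slot ``round((t - t0)/delta_min)`` (ties away from zero).
    Slots between 0 and the last assigned slot that receive no record are
    explicit missing cells.  When two records land in one slot the earlier
    is kept and the later dropped (logged, counted on the person grid).
    """
    if delta_min <= 0:
        raise ValueError("delta_min must be positive")
    codes = panel.catalog.codes
    persons = []
    for pid, sub in panel.data.groupby("person_id", sort=False):
        ans = sub[sub["answered"].astype(bool)]
        if ans.empty:
            logger.warning("person %s has no answered records; dropped", pid)
            continue
        t = ans["t_min"].to_numpy(dtype=float)
        t0 = t[0]
        # round half away from zero; offsets are nonnegative by construction
        slots = np.floor((t - t0) / delta_min + 0.5).astype(int)
        n_slots = int(slots.max()) + 1
        values = np.full((n_slots, len(codes)), np.nan)
        scores = ans[codes].to_numpy(dtype=float)
        n_coll = 0
        filled = np.zeros(n_slots, dtype=bool)
        for r, s in enumerate(slots):
            if filled[s]:
                n_coll += 1
                logger.info("person %s: record at t=%.1f collides in slot %d; dropped",
                            pid, t[r], s)
                continue
            values[s] = scores[r]
            filled[s] = True
        persons.append(PersonGrid(person_id=pid, group=ans["group"].iloc[0],
                                  values=values, delta_min=float(delta_min),
                                  t0_min=float(t0), n_collisions=n_coll))
    return GriddedPanel(persons=persons, delta_min=float(delta_min),
                        item_codes=codes, catalog=panel.catalog)


class GridAligner(TransformerMixin, BaseEstimator):
    """Transformer wrapper around :func:`align_to_grid`.

    Stateless; ``fit`` only validates, so the aligner drops into sklearn
    pipelines ahead of the model estimator.
    """

    def __init__(self, delta_min: float = 180.0):
        self.delta_min = delta_min

    def fit(self, X: EmaPanel, y=None):
        if self.delta_min <= 0:
            raise ValueError("delta_min must be positive")
        self.n_persons_in_ = X.n_persons
        return self

    def transform(self, X: EmaPanel) -> GriddedPanel:
        return align_to_grid(X, delta_min=self.delta_min)


def descriptives(panel: EmaPanel) -> pd.DataFrame:
    """Per group x item: endorsement and within/between-person moments.

    percent_endorsed is the group mean of each person's proportion of
    answered scores >= 2 (x100); person means are summarised by their mean
    and SD over persons; within-person SDs likewise (persons with fewer
    than two answered records contribute no SD).
    Requires a reverse-coded panel.
    """
    if not panel.coded:
        raise ValueError("descriptives expects a reverse-coded panel")
    ans = panel.answered_data()
    rows = []
    for group in panel.data["group"].unique():
        g = ans[ans["group"] == group]
        if g.empty:
            raise ValueError(f"group {group!r} has no answered records")
        for code in panel.catalog.codes:
            per = g.groupby("person_id")[code]
            endorsed = per.apply(lambda s: np.mean(s >= 2) * 100.0)
            pmeans = per.mean()
            psds = per.std(ddof=1).dropna()
            rows.append({
                "group": group, "item": code,
                "percent_endorsed": endorsed.mean(),
                "person_mean": pmeans.mean(),
                "person_mean_sd": pmeans.std(ddof=1),
                "within_person_sd": psds.mean(),
                "within_person_sd_sd": psds.std(ddof=1),
            })
    return pd.DataFrame(rows)


_KPSS_ALPHA_KEYS = {0.10: "10%", 0.05: "5%", 0.025: "2.5%", 0.01: "1%"}


def kpss_stat(x: np.ndarray) -> tuple:
    """Level-stationarity KPSS statistic with automatic lag truncation.

    Returns ``(statistic, critical_values)``.  A constant series has zero
    partial-sum variance; its statistic is defined as 0 (stationary).
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0.0:
        return 0.0, dict(_sm_crit_values())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", InterpolationWarning)
        stat, _, _, crit = _sm_kpss(x, regression="c", nlags="auto")
    return float(stat), crit


def _sm_crit_values() -> dict:
    return {"10%": 0.347, "5%": 0.463, "2.5%": 0.574, "1%": 0.739}


def kpss_screen(gridded: GriddedPanel, alpha: float = 0.05,
                min_points: int = 20) -> dict:
    """KPSS level-stationarity screen per person x item.

    Missing cells are dropped and the test run on the observed subsequence.
    Series shorter than ``min_points`` are marked untestable and excluded
    from the per-item stationary fraction's denominator.

    Returns ``{"table": per person x item frame, "fractions": per item}``.
    """
    if alpha not in _KPSS_ALPHA_KEYS:
        raise ValueError(f"alpha must be one of {sorted(_KPSS_ALPHA_KEYS)}")
    key = _KPSS_ALPHA_KEYS[alpha]
    rows = []
    for pg in gridded.persons:
        for j, code in enumerate(gridded.item_codes):
            x = pg.values[:, j]
            x = x[np.isfinite(x)]
            if x.size < min_points:
                rows.append({"person_id": pg.person_id, "item": code,
                             "statistic": np.nan, "stationary": np.nan,
                             "testable": False})
                continue
            stat, crit = kpss_stat(x)
            rows.append({"person_id": pg.person_id, "item": code,
                         "statistic": stat, "stationary": bool(stat < crit[key]),
                         "testable": True})
    table = pd.DataFrame(rows)
    testable = table[table["testable"]]
    fractions = (testable.groupby("item")["stationary"].mean()
                 .reindex(gridded.item_codes))
    return {"table": table, "fractions": fractions}


def collinearity_check(gridded: GriddedPanel, threshold: float = 0.9) -> dict:
    """Pooled within-person (person-mean-centred) Pearson correlations.

    Flags the panel when any off-diagonal |r| exceeds ``threshold``.
    """
    blocks = []
    for pg in gridded.persons:
        obs = pg.values[np.isfinite(pg.values).all(axis=1)]
        if obs.shape[0] < 2:
            continue
        blocks.append(obs - obs.mean(axis=0))
    pooled = np.vstack(blocks)
    corr = pd.DataFrame(np.corrcoef(pooled, rowvar=False),
                        index=gridded.item_codes, columns=gridded.item_codes)
    off = corr.to_numpy().copy()
    np.fill_diagonal(off, 0.0)
    max_abs = float(np.nanmax(np.abs(off)))
    return {"correlations": corr, "max_abs_r": max_abs,
            "flag": bool(max_abs > threshold)}
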