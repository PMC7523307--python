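"""Synthetic EMA panel generator.

Simulates momentary mental-state panels with the structure the downstream
model assumes: a stationary person-level VAR(1) on an equally spaced
minute lattice, person random effects around group-average dynamics, a
fixed daily sampling scheme (several prompts per day, a long night gap),
missed prompts, and optional Likert discretisation.

The default configuration mimics a three-group clinical EMA design
(comorbid depression+anxiety, depression-only, anxiety-only; 143/40/37
persons; 5 prompts/day at 3-h intervals for 14 days).  The group lag
matrices and item means are illustrative values shaped like published
group networks and descriptives — they are a qualitative emulation, not
estimates of any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov

from .catalog import ItemCatalog, default_catalog
from .panel import GROUPS, EmaPanel

__all__ = [
    "ScheduleSpec",
    "GroupSpec",
    "GeneratorConfig",
    "build_schedule",
    "draw_person_params",
    "simulate_person",
    "simulate_panel",
    "default_config",
    "spectral_radius",
]

MAX_STATIONARITY_RETRIES = 100


def spectral_radius(phi: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(phi))))


@dataclass(frozen=True)
class ScheduleSpec:
    """Daily prompt scheme: ``prompts_per_day`` prompts at ``interval_min``
    spacing each day for ``days`` days; prompt times jittered by a truncated
    normal with SD ``jitter_sd_min`` (clipped to +-45% of the interval so
    prompts keep their order and lattice slot)."""

    days: int = 14
    prompts_per_day: int = 5
    interval_min: float = 180.0
    jitter_sd_min: float = 0.0

    def __post_init__(self) -> None:
        if self.days < 1 or self.prompts_per_day < 1:
            raise ValueError("days and prompts_per_day must be >= 1")
        if self.interval_min <= 0:
            raise ValueError("interval_min must be positive")
        day_span = (self.prompts_per_day - 1) * self.interval_min
        if self.prompts_per_day > 1 and day_span >= 1440.0:
            raise ValueError(
                f"within-day prompts overlap the next day: span {day_span} min >= 1440"
            )

    @property
    def n_prompts(self) -> int:
        return self.days * self.prompts_per_day


@dataclass(frozen=True)
class GroupSpec:
    """Group-average dynamics: lag matrix (rows = destination item), item
    means on the coded 1-7 scale, and group size."""

    phi_mean: np.ndarray
    mu_mean: np.ndarray
    n_persons: int

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi_mean, dtype=float)
        mu = np.asarray(self.mu_mean, dtype=float)
        if phi.ndim != 2 or phi.shape[0] != phi.shape[1]:
            raise ValueError("phi_mean must be square")
        if mu.shape != (phi.shape[0],):
            raise ValueError("mu_mean length must match phi_mean dimension")
        if spectral_radius(phi) >= 1.0:
            raise ValueError(
                f"phi_mean is non-stationary (spectral radius {spectral_radius(phi):.3f} >= 1)"
            )
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        object.__setattr__(self, "phi_mean", phi)
        object.__setattr__(self, "mu_mean", mu)


@dataclass(frozen=True)
class GeneratorConfig:
    group_specs: dict               # group label -> GroupSpec, insertion-ordered
    innovation_cov: np.ndarray
    schedule: ScheduleSpec = field(default_factory=ScheduleSpec)
    re_sd_phi: float = 0.05
    re_sd_mu: float = 0.6
    miss_prob: float = 0.08
    likert: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        cov = np.asarray(self.innovation_cov, dtype=float)
        if not np.allclose(cov, cov.T) or np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("innovation_cov must be symmetric positive definite")
        if not (0.0 <= self.miss_prob < 1.0):
            raise ValueError("miss_prob must be in [0, 1)")
        if self.re_sd_phi < 0 or self.re_sd_mu < 0:
            raise ValueError("random-effect SDs must be nonnegative")
        object.__setattr__(self, "innovation_cov", cov)

    @property
    def n_items(self) -> int:
        return self.innovation_cov.shape[0]

    @property
    def n_persons_total(self) -> int:
        return sum(gs.n_persons for gs in self.group_specs.values())

    def to_dict(self) -> dict:
        return {
            "groups": {
                g: {
                    "phi_mean": gs.phi_mean.tolist(),
                    "mu_mean": gs.mu_mean.tolist(),
                    "n_persons": gs.n_persons,
                }
                for g, gs in self.group_specs.items()
            },
            "innovation_cov": self.innovation_cov.tolist(),
            "schedule": {
                "days": self.schedule.days,
                "prompts_per_day": self.schedule.prompts_per_day,
                "interval_min": self.schedule.interval_min,
                "jitter_sd_min": self.schedule.jitter_sd_min,
            },
            "re_sd_phi": self.re_sd_phi,
            "re_sd_mu": self.re_sd_mu,
            "miss_prob": self.miss_prob,
            "likert": self.likert,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(
            group_specs={
                g: GroupSpec(
                    phi_mean=np.asarray(s["phi_mean"], dtype=float),
                    mu_mean=np.asarray(s["mu_mean"], dtype=float),
                    n_persons=int(s["n_persons"]),
                )
                for g, s in d["groups"].items()
            },
            innovation_cov=np.asarray(d["innovation_cov"], dtype=float),
            schedule=ScheduleSpec(**d.get("schedule", {})),
            re_sd_phi=float(d.get("re_sd_phi", 0.05)),
            re_sd_mu=float(d.get("re_sd_mu", 0.6)),
            miss_prob=float(d.get("miss_prob", 0.08)),
            likert=bool(d.get("likert", False)),
            seed=int(d.get("seed", 0)),
        )


# --------------------------------------------------------------------------
# scheduling


def build_schedule(spec: ScheduleSpec, seed=None) -> np.ndarray:
    """Prompt times in minutes since the first prompt.

    Day ``d`` prompt ``k`` sits at ``1440*d + interval_min*k`` plus jitter;
    the very first prompt anchors the origin at 0.  Jitter is clipped to
    +-45% of the interval, which keeps gaps positive and each prompt nearest
    to its own lattice slot.
    """
    rng = np.random.default_rng(seed)
    d = np.arange(spec.days)[:, None]
    k = np.arange(spec.prompts_per_day)[None, :]
    times = (1440.0 * d + spec.interval_min * k).ravel()
    if spec.jitter_sd_min > 0:
        lim = 0.45 * spec.interval_min
        jit = np.clip(rng.normal(0.0, spec.jitter_sd_min, size=times.size), -lim, lim)
        jit[0] = 0.0
        times = times + jit
    assert np.all(np.diff(times) > 0)
    return times


# --------------------------------------------------------------------------
# person-level simulation


def draw_person_params(group_spec: GroupSpec, re_sd_phi: float, re_sd_mu: float,
                       seed=None, max_retries: int = MAX_STATIONARITY_RETRIES):
    """Draw one person's lag matrix and means around the group averages.

    Entries deviate independently Normal(group value, re_sd^2); a draw whose
    lag matrix is non-stationary is rejected and redrawn.

    Returns
    -------
    phi_i, mu_i, n_retries
    """
    rng = np.random.default_rng(seed)
    p = group_spec.mu_mean.shape[0]
    mu_i = group_spec.mu_mean + rng.normal(0.0, re_sd_mu, size=p)
    for n_retries in range(max_retries + 1):
        phi_i = group_spec.phi_mean + rng.normal(0.0, re_sd_phi, size=(p, p))
        if spectral_radius(phi_i) < 1.0:
            return phi_i, mu_i, n_retries
    raise RuntimeError(
        f"could not draw a stationary person lag matrix after {max_retries} retries "
        f"(group phi spectral radius {spectral_radius(group_spec.phi_mean):.3f}, "
        f"re_sd_phi={re_sd_phi})"
    )


def stationary_cov(phi: np.ndarray, innovation_cov: np.ndarray) -> np.ndarray:
    """Long-run covariance of the VAR(1): solves V = phi V phi' + Sigma."""
    if spectral_radius(phi) >= 1.0:
        raise ValueError("phi is non-stationary; no stationary distribution")
    v = solve_discrete_lyapunov(phi, innovation_cov)
    # symmetrise + jitter so downstream Cholesky factorisations are safe
    return 0.5 * (v + v.T) + 1e-10 * np.eye(v.shape[0])


def simulate_person(phi_i, mu_i, innovation_cov, prompt_times, interval_min,
                    miss_prob=0.0, likert=False, seed=None) -> pd.DataFrame:
    """Simulate one person's records at the given prompt times.

    The latent process lives on the ``interval_min`` lattice and keeps
    evolving through unprompted slots (nights, missed prompts); each prompt
    is read off at its nearest lattice slot.  Returns a frame with columns
    ``t_min, answered, y0..y{p-1}`` on the coded scale.
    """
    phi_i = np.asarray(phi_i, dtype=float)
    mu_i = np.asarray(mu_i, dtype=float)
    cov = np.asarray(innovation_cov, dtype=float)
    prompt_times = np.asarray(prompt_times, dtype=float)
    rng = np.random.default_rng(seed)
    p = mu_i.shape[0]

    slots = np.rint(prompt_times / interval_min).astype(int)
    n_slots = int(slots.max()) + 1

    v0 = stationary_cov(phi_i, cov)
    z = np.empty((n_slots, p))
    z[0] = rng.multivariate_normal(np.zeros(p), v0, method="cholesky")
    eps = rng.multivariate_normal(np.zeros(p), cov, size=max(n_slots - 1, 1),
                                  method="cholesky")
    for t in range(1, n_slots):
        z[t] = phi_i @ z[t - 1] + eps[t - 1]
    y = mu_i + z[slots]

    answered = rng.random(prompt_times.size) >= miss_prob
    if likert:
        y = np.clip(np.rint(y), 1.0, 7.0)
    y = np.where(answered[:, None], y, np.nan)
    out = pd.DataFrame(y, columns=[f"y{j}" for j in range(p)])
    out.insert(0, "t_min", prompt_times)
    out.insert(1, "answered", answered)
    return out


# --------------------------------------------------------------------------
# panel assembly

_GROUP_PREFIX = {"comorbid": "com", "depression_only": "dep", "anxiety_only": "anx"}

# fraction of persons with a recent (<6 months) diagnosis, by group
_RECENT_PROB = {"comorbid": 0.52, "depression_only": 0.20, "anxiety_only": 0.32}


def simulate_panel(config: GeneratorConfig, catalog: ItemCatalog | None = None) -> EmaPanel:
    """Simulate the full multi-group panel.

    Items whose catalog entry is reverse coded are emitted on the raw
    questionnaire scale (``8 - coded value``), so the panel arrives uncoded
    exactly as real exports would; severity and recency metadata are
    synthesised per person to exercise subgroup filters (severity is a noisy
    monotone function of the person's latent symptom level).
    """
    catalog = catalog or default_catalog()
    if len(catalog) != config.n_items:
        raise ValueError("catalog size does not match config dimension")
    unknown = set(config.group_specs) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown groups in config: {sorted(unknown)}")

    root = np.random.SeedSequence(config.seed)
    frames, meta_rows = [], []
    rev = np.array([it.reverse_coded for it in catalog])
    for group, gspec in config.group_specs.items():
        gseq = root.spawn(1)[0]
        person_seqs = gseq.spawn(3 * gspec.n_persons)
        for i in range(gspec.n_persons):
            pid = f"{_GROUP_PREFIX[group]}{i + 1:03d}"
            sched_seq, param_seq, sim_seq = person_seqs[3 * i: 3 * i + 3]
            times = build_schedule(config.schedule, seed=sched_seq)
            try:
                phi_i, mu_i, _ = draw_person_params(
                    gspec, config.re_sd_phi, config.re_sd_mu, seed=param_seq)
                rec = simulate_person(
                    phi_i, mu_i, config.innovation_cov, times,
                    config.schedule.interval_min, miss_prob=config.miss_prob,
                    likert=config.likert, seed=sim_seq)
            except Exception as exc:  # re-raise with person context
                raise RuntimeError(f"simulation failed for person {pid} in group {group}") from exc
            ycols = [f"y{j}" for j in range(config.n_items)]
            scores = rec[ycols].to_numpy()
            scores[:, rev] = 8.0 - scores[:, rev]  # back to raw questionnaire scale
            frame = pd.DataFrame(scores, columns=catalog.codes)
            frame.insert(0, "person_id", pid)
            frame.insert(1, "group", group)
            frame.insert(2, "t_min", rec["t_min"].to_numpy())
            frame.insert(3, "answered", rec["answered"].to_numpy())
            frames.append(frame)

            meta_rng = np.random.default_rng(param_seq.spawn(1)[0])
            severity = float(np.clip(12.0 * (mu_i.mean() - 1.0) + meta_rng.normal(0.0, 4.0), 0.0, 84.0))
            recency = "recent" if meta_rng.random() < _RECENT_PROB[group] else "past"
            meta_rows.append({"person_id": pid, "group": group,
                              "severity": severity, "recency_class": recency})

    data = pd.concat(frames, ignore_index=True)
    metadata = pd.DataFrame(meta_rows)
    return EmaPanel(data=data, catalog=catalog, metadata=metadata,
                    coded=False, likert=config.likert)


# --------------------------------------------------------------------------
# default configuration

# Item order: REL, CHE, IRR, LIS, DOW, NER, WOR (catalog order).
# Lag matrices are illustrative: all-positive effects, autoregressions
# ~0.2-0.36, a denser comorbid network, and cross-cluster paths through the
# overlapping items.  Rows are destinations: phi[i, j] = effect of item j at
# t-1 on item i at t.

_PHI_COMORBID = np.array([
    # REL   CHE   IRR   LIS   DOW   NER   WOR
    [0.25, 0.00, 0.00, 0.00, 0.00, 0.10, 0.07],  # REL <-
    [0.00, 0.22, 0.00, 0.06, 0.09, 0.00, 0.00],  # CHE <-
    [0.00, 0.00, 0.22, 0.00, 0.05, 0.06, 0.00],  # IRR <-
    [0.00, 0.05, 0.00, 0.26, 0.07, 0.00, 0.06],  # LIS <-
    [0.00, 0.08, 0.06, 0.08, 0.28, 0.00, 0.09],  # DOW <-
    [0.07, 0.00, 0.00, 0.00, 0.00, 0.24, 0.08],  # NER <-
    [0.06, 0.00, 0.00, 0.07, 0.10, 0.09, 0.30],  # WOR <-
])

_PHI_DEP_ONLY = np.array([
    [0.24, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00],
    [0.00, 0.20, 0.00, 0.00, 0.08, 0.00, 0.00],
    [0.00, 0.00, 0.18, 0.00, 0.00, 0.00, 0.00],
    [0.00, 0.00, 0.00, 0.22, 0.08, 0.00, 0.00],
    [0.00, 0.06, 0.00, 0.09, 0.25, 0.00, 0.00],
    [0.00, 0.00, 0.00, 0.00, 0.00, 0.18, 0.07],
    [0.00, 0.00, 0.00, 0.06, 0.10, 0.00, 0.26],
])

_PHI_ANX_ONLY = np.array([
    [0.26, 0.13, 0.00, 0.00, 0.00, 0.09, 0.07],
    [0.06, 0.21, 0.00, 0.00, 0.00, 0.00, 0.00],
    [0.00, 0.00, 0.20, 0.00, 0.00, 0.06, 0.00],
    [0.00, 0.05, 0.00, 0.22, 0.00, 0.00, 0.00],
    [0.00, 0.06, 0.00, 0.00, 0.24, 0.05, 0.00],
    [0.08, 0.00, 0.00, 0.00, 0.00, 0.26, 0.08],
    [0.06, 0.00, 0.05, 0.00, 0.00, 0.09, 0.36],
])

_MU = {
    "comorbid": np.array([3.52, 3.66, 2.09, 2.48, 2.43, 2.22, 3.02]),
    "depression_only": np.array([2.84, 3.03, 1.48, 1.75, 1.50, 1.37, 1.76]),
    "anxiety_only": np.array([3.09, 3.01, 1.70, 1.72, 1.47, 1.77, 2.19]),
}

# within-person innovation scale per item, with a mild shared correlation
_INNOV_SD = np.array([1.00, 0.90, 0.95, 0.90, 0.78, 0.82, 0.85])
_INNOV_CORR = 0.3


def default_innovation_cov() -> np.ndarray:
    corr = np.full((7, 7), _INNOV_CORR) + (1.0 - _INNOV_CORR) * np.eye(7)
    return corr * np.outer(_INNOV_SD, _INNOV_SD)


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Three-group study-scale configuration (143/40/37 persons, 5x14 design).

    ``overrides`` may replace top-level fields (e.g. ``miss_prob=0``) or
    supply ``n_persons`` as a dict group->count to rescale group sizes.
    """
    n_persons = overrides.pop("n_persons", {"comorbid": 143, "depression_only": 40,
                                            "anxiety_only": 37})
    phis = {"comorbid": _PHI_COMORBID, "depression_only": _PHI_DEP_ONLY,
            "anxiety_only": _PHI_ANX_ONLY}
    group_specs = {
        g: GroupSpec(phi_mean=phis[g], mu_mean=_MU[g], n_persons=n_persons[g])
        for g in n_persons
    }
    kwargs = dict(group_specs=group_specs, innovation_cov=default_innovation_cov(),
                  schedule=ScheduleSpec(jitter_sd_min=10.0), seed=seed)
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)
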