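"""End-to-end pipeline: generate/load -> preprocess -> fit -> bridges -> report.

Every stage is seeded from the manifest seed, stage outputs are written as
tidy CSV/JSON under the output directory, and a run manifest records the
config hash, seeds, per-stage row counts, convergence summary and a
checksum for every file produced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bridge import compare_groups, enumerate_bridge_paths, bridge_effect_draws, \
    rank_bridges, summarize_effect
from .catalog import ItemCatalog, default_catalog
from .mlvar import MlvarSpec, edge_density, edge_summaries, fit_mlvar, \
    group_phi_draws, psr_diagnostic
from .panel import EmaPanel
from .preprocess import align_to_grid, collinearity_check, descriptives, \
    kpss_screen, reverse_code
from .simulate import GeneratorConfig, GroupSpec, ScheduleSpec, default_config, \
    simulate_panel

logger = logging.getLogger(__name__)

__all__ = [
    "SubgroupFilter",
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "filter_subgroup",
    "make_fixtures",
    "true_bridge_effect",
]


@dataclass(frozen=True)
class SubgroupFilter:
    """Metadata predicate applied to one group; other groups pass through.

    ``severity_tertile`` keeps persons of the target group in the named
    sample-severity tertile (boundaries at the 1/3 and 2/3 quantiles of the
    target group's severity, ties going to the lower tertile);
    ``recency_in`` keeps persons whose recency class is in the allowed set.
    """

    name: str
    group: str = "comorbid"
    severity_tertile: str | None = None       # low | mid | high
    recency_in: tuple | None = None

    def __post_init__(self) -> None:
        if self.severity_tertile not in (None, "low", "mid", "high"):
            raise ValueError("severity_tertile must be low, mid or high")
        if self.recency_in is not None:
            object.__setattr__(self, "recency_in", tuple(self.recency_in))


def filter_subgroup(panel: EmaPanel, spec: SubgroupFilter) -> EmaPanel:
    """Retain target-group persons matching the predicate; other groups pass."""
    if spec.severity_tertile is None and spec.recency_in is None:
        return panel
    if panel.metadata is None:
        raise ValueError(f"subgroup filter {spec.name!r} needs panel metadata")
    meta = panel.metadata
    required = []
    if spec.severity_tertile is not None:
        required.append("severity")
    if spec.recency_in is not None:
        required.append("recency_class")
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise KeyError(f"subgroup filter {spec.name!r}: metadata lacks {missing}")

    target = meta[meta["group"] == spec.group].copy()
    keep = pd.Series(True, index=target.index)
    if spec.severity_tertile is not None:
        sev = target["severity"].to_numpy(dtype=float)
        q1, q2 = np.quantile(sev, [1 / 3, 2 / 3])
        if spec.severity_tertile == "low":
            keep &= target["severity"] <= q1
        elif spec.severity_tertile == "mid":
            keep &= (target["severity"] > q1) & (target["severity"] <= q2)
        else:
            keep &= target["severity"] > q2
    if spec.recency_in is not None:
        keep &= target["recency_class"].isin(spec.recency_in)
    kept_target = set(target.loc[keep, "person_id"])
    if not kept_target:
        raise ValueError(f"subgroup filter {spec.name!r} matched nobody in "
                         f"group {spec.group!r}")
    others = set(meta.loc[meta["group"] != spec.group, "person_id"])
    return panel.subset_persons(kept_target | others)


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig | None = None
    panel_path: str | None = None
    delta_min: float = 180.0
    mlvar: MlvarSpec = field(default_factory=MlvarSpec)
    candidate_bridges: tuple | str = "all"
    hypothesized_bridges: tuple = ("WOR", "IRR")
    subgroups: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generator is None and self.panel_path is None:
            object.__setattr__(self, "generator", default_config(seed=self.seed))

    def resolve_bridges(self, catalog: ItemCatalog) -> list:
        if self.candidate_bridges == "all":
            return list(catalog.codes)
        unknown = set(self.candidate_bridges) - set(catalog.codes)
        if unknown:
            raise ValueError(f"candidate bridges not in catalog: {sorted(unknown)}")
        return list(self.candidate_bridges)

    # ------------------------------------------------------------ yaml I/O

    def to_dict(self) -> dict:
        return {
            "generator": self.generator.to_dict() if self.generator else None,
            "panel_path": self.panel_path,
            "delta_min": self.delta_min,
            "mlvar": asdict(self.mlvar),
            "candidate_bridges": (self.candidate_bridges
                                  if self.candidate_bridges == "all"
                                  else list(self.candidate_bridges)),
            "hypothesized_bridges": list(self.hypothesized_bridges),
            "subgroups": [asdict(s) for s in self.subgroups],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        gen = d.get("generator")
        subs = tuple(SubgroupFilter(**s) for s in d.get("subgroups", []))
        cand = d.get("candidate_bridges", "all")
        return cls(
            generator=GeneratorConfig.from_dict(gen) if gen else None,
            panel_path=d.get("panel_path"),
            delta_min=float(d.get("delta_min", 180.0)),
            mlvar=MlvarSpec(**d.get("mlvar", {})),
            candidate_bridges=cand if cand == "all" else tuple(cand),
            hypothesized_bridges=tuple(d.get("hypothesized_bridges", ("WOR", "IRR"))),
            subgroups=subs,
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        from pathlib import Path
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        from pathlib import Path
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)
    psr: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)
    subgroup: str | None = None

    def write(self, path) -> None:
        from pathlib import Path
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir, subgroup: str | None = None,
                 catalog: ItemCatalog | None = None) -> RunManifest:
    """Execute all stages; returns the manifest (also written to the out dir).

    ``subgroup`` names one of ``config.subgroups`` for a sensitivity rerun:
    the panel is filtered and the model refitted on the filtered panel.
    """
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = catalog or default_catalog()
    manifest = RunManifest(config_hash=_config_hash(config), seed=config.seed,
                           version=__version__, subgroup=subgroup)

    def stage(name, rows_in, rows_out, t0):
        manifest.stages[name] = {"rows_in": int(rows_in), "rows_out": int(rows_out),
                                 "seconds": round(time.time() - t0, 2)}
        logger.info("stage %-10s rows_in=%d rows_out=%d (%.1fs)",
                    name, rows_in, rows_out, time.time() - t0)

    try:
        # ------------------------------------------------ simulate / load
        t0 = time.time()
        if config.panel_path:
            panel = EmaPanel.read_csv(config.panel_path, catalog=catalog)
        else:
            # the manifest seed governs every stochastic stage
            gen = GeneratorConfig.from_dict({**config.generator.to_dict(),
                                             "seed": config.seed})
            panel = simulate_panel(gen, catalog=catalog)
        panel.write_csv(out / "panel.csv",
                        sidecar={"seed": config.seed,
                                 "generator": (config.generator.to_dict()
                                               if config.generator else None)})
        stage("input", 0, len(panel.data), t0)

        if subgroup is not None:
            spec = next((s for s in config.subgroups if s.name == subgroup), None)
            if spec is None:
                raise KeyError(f"unknown subgroup {subgroup!r}; configured: "
                               f"{[s.name for s in config.subgroups]}")
            t0 = time.time()
            n_in = len(panel.data)
            panel = filter_subgroup(panel, spec)
            stage("subgroup", n_in, len(panel.data), t0)

        # ------------------------------------------------ preprocess
        t0 = time.time()
        coded = reverse_code(panel) if not panel.coded else panel
        gridded = align_to_grid(coded, delta_min=config.delta_min)
        desc = descriptives(coded)
        desc.to_csv(out / "descriptives.csv", index=False)
        kp = kpss_screen(gridded)
        kp["table"].to_csv(out / "kpss.csv", index=False)
        kp["fractions"].rename("fraction_stationary").to_csv(out / "kpss_fractions.csv")
        coll = collinearity_check(gridded)
        coll["correlations"].to_csv(out / "collinearity.csv")
        gridded.write_csv(out / "gridded.csv")
        stage("preprocess", len(panel.data), sum(p.n_slots for p in gridded.persons), t0)

        # ------------------------------------------------ fit
        t0 = time.time()
        spec = MlvarSpec(**{**asdict(config.mlvar), "seed": config.seed + 1})
        draws = fit_mlvar(gridded, spec)
        psr = psr_diagnostic(draws, threshold=spec.psr_threshold)
        psr.to_csv(out / "psr.csv", index=False)
        manifest.psr = {"max_psr": float(psr["psr"].max()),
                        "n_above_threshold": int((~psr["ok"]).sum()),
                        "threshold": spec.psr_threshold}
        edges = edge_summaries(draws)
        edges.to_csv(out / "edges.csv", index=False)
        edge_density(edges).to_csv(out / "edge_density.csv", index=False)
        stage("fit", len(gridded.persons), len(edges), t0)

        # ------------------------------------------------ bridges
        t0 = time.time()
        candidates = config.resolve_bridges(catalog)
        summaries = {}   # (bridge, group) -> BridgeEffectSummary
        rows = []
        for group in draws.groups:
            phi = group_phi_draws(draws, group)
            for code in candidates:
                ps = enumerate_bridge_paths(code, catalog)
                s = summarize_effect(bridge_effect_draws(phi, ps, catalog),
                                     ps.count, bridge=code, group=group)
                summaries[(code, group)] = s
                rows.append(s.as_row())
        bridges_df = pd.DataFrame(rows)
        bridges_df.to_csv(out / "bridges.csv", index=False)

        diff_rows = []
        ref = draws.groups[0]
        for code in config.hypothesized_bridges:
            if code not in candidates:
                continue
            for other in draws.groups[1:]:
                d = compare_groups(summaries[(code, ref)], summaries[(code, other)])
                diff_rows.append(d.as_row())
        diffs_df = pd.DataFrame(diff_rows)
        diffs_df.to_csv(out / "differences.csv", index=False)

        rank_frames = []
        for group in draws.groups:
            per_group = [summaries[(c, group)] for c in candidates]
            rank_frames.append(rank_bridges(per_group, catalog))
        ranking_df = pd.concat(rank_frames, ignore_index=True)
        ranking_df.to_csv(out / "ranking.csv", index=False)
        stage("bridges", len(candidates) * len(draws.groups),
              len(rows) + len(diff_rows), t0)

        # ------------------------------------------------ report
        t0 = time.time()
        report = {
            "groups": draws.groups,
            "edge_density": edge_density(edges).to_dict(orient="records"),
            "bridges": bridges_df.to_dict(orient="records"),
            "differences": diffs_df.to_dict(orient="records"),
            "ranking": ranking_df.to_dict(orient="records"),
            "kpss_fraction_stationary": {k: (None if pd.isna(v) else float(v))
                                         for k, v in kp["fractions"].items()},
            "collinearity_flag": coll["flag"],
            "psr": manifest.psr,
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        stage("report", len(rows), len(report["bridges"]), t0)
    except Exception:
        manifest.write(out / "manifest.json")  # persist partial manifest
        raise

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest.files[f.name] = _sha256(f)
    manifest.write(out / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# truth oracle + fixtures


def true_bridge_effect(phi: np.ndarray, bridge: str, catalog: ItemCatalog) -> float:
    """Brute-force bridge effect of a known lag matrix.

    Triple loop applying the membership rule directly; independent of the
    path enumerator, usable as a recovery-test reference.
    """
    b = catalog.index(bridge)
    total = 0.0
    for i, it_i in enumerate(catalog):
        for j, it_j in enumerate(catalog):
            if i == j or i == b or j == b:
                continue
            crosses = any(x != y for x in it_i.membership for y in it_j.membership)
            if crosses:
                total += phi[b, i] * phi[j, b]
    return total


_FIXTURE_SCALES = {
    "tiny": {"n_persons": {"comorbid": 2, "depression_only": 2, "anxiety_only": 2},
             "schedule": ScheduleSpec(days=4, prompts_per_day=5, interval_min=180.0)},
    "small": {"n_persons": {"comorbid": 30, "depression_only": 30, "anxiety_only": 30},
              "schedule": ScheduleSpec(days=14, prompts_per_day=5, interval_min=180.0,
                                       jitter_sd_min=10.0)},
}


def make_fixtures(scale: str, seed: int = 0) -> dict:
    """Deterministic test panels with oracle bridge effects.

    ``tiny``: 6 persons x 20 prompts for unit tests; ``small``: 30
    persons/group x 70 prompts for integration tests.  The returned dict
    carries the panel, its generator config and the generator-truth bridge
    effect of every item in every group (brute-force pair-sum oracle).
    """
    if scale not in _FIXTURE_SCALES:
        raise ValueError(f"scale must be one of {sorted(_FIXTURE_SCALES)}")
    opts = _FIXTURE_SCALES[scale]
    cfg = default_config(seed=seed, n_persons=opts["n_persons"],
                         schedule=opts["schedule"], re_sd_phi=0.05)
    catalog = default_catalog()
    panel = simulate_panel(cfg, catalog=catalog)
    truth = {
        group: {code: true_bridge_effect(gs.phi_mean, code, catalog)
                for code in catalog.codes}
        for group, gs in cfg.group_specs.items()
    }
    return {"panel": panel, "config": cfg, "true_bridge_effects": truth,
            "catalog": catalog}
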