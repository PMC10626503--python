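"""End-to-end orchestration: simulate -> screen -> fit -> compare -> timescales.

Each stage writes plain-text artifacts (CSV tables, YAML specs) into the
output directory and later stages read only those artifacts, so a run can be
resumed or partially rerun.  All stage parameters live in
:class:`PipelineConfig`; the defaults are the study's standard values
(100 shuffles, AIC support threshold 10, 0.15-0.5 s reaction-time window,
subpopulations of 4 neurons, 50 timescale samples, 100 bootstraps, 25 ms
autocorrelation bins, 5 ms selectivity bins, 100/50 ms boxcars).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from evacc import __version__
from evacc import accumulators as acc
from evacc import model_selection as ms
from evacc import selectivity as sel
from evacc import timescales as ts
from evacc.datasets import SpikeDataset, read_dataset, write_dataset
from evacc.dpca import build_marginalized_tensor, cluster_neurons, fit_dpca
from evacc.laplace_em import fit_laplace_em
from evacc.synthetic import make_task_trials, make_selectivity_cohort, simulate_accumulator_dataset

log = logging.getLogger("evacc.pipeline")


@dataclass
class RegionSpec:
    """Synthetic-region recipe: one accumulator microcircuit per region."""

    name: str = "region"
    kind: str = "single"
    A_acc: float = 0.98
    V_acc: float = 0.05
    Q_acc: float = 0.02  # step noise giving mouse-like psychometric lapses
    n_neurons: int = 12
    n_trials: int = 300
    n_distractors: int = 6  # stimulus-only neurons mixed in


_REGION_FIELDS = {f.name for f in dataclasses.fields(RegionSpec)}


@dataclass
class PipelineConfig:
    """All pipeline stages' tunables, defaulting to the standard values."""

    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate", "dpca", "selectivity", "fit", "compare", "timescales"
    )
    regions: list[RegionSpec] = field(
        default_factory=lambda: [
            RegionSpec(name="areaA", A_acc=0.97),
            RegionSpec(name="areaB", A_acc=0.99),
        ]
    )
    n_shuffles: int = 100
    aic_threshold: float = 10.0
    rt_range: tuple[float, float] = (0.15, 0.5)
    subpop_size: int = 4
    n_subpops_per_region: int = 20
    timescale_samples: int = 50
    timescale_trials: int = 1000
    n_boot: int = 100
    autocorr_delta: float = 0.025
    bin_size: float = 0.005
    fit_dt: float = 0.01
    latency_boxcar: float = 0.1
    rate_boxcar: float = 0.05
    latency: float = 0.1
    n_em: int = 25
    init_grid: list[dict] | None = None  # None -> full standard grids
    aic_samples: int = 100
    onset_delay: float = 0.1

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data = dict(data)
        if "regions" in data:
            regions = []
            for r in data["regions"]:
                bad = set(r) - _REGION_FIELDS
                if bad:
                    raise ValueError(f"unknown config key(s): {sorted(bad)}")
                regions.append(RegionSpec(**r))
            data["regions"] = regions
        if "rt_range" in data:
            data["rt_range"] = tuple(data["rt_range"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = [dataclasses.asdict(r) for r in self.regions]
        d["stages"] = list(self.stages)
        d["rt_range"] = list(self.rt_range)
        return d

    def overrides(self) -> dict:
        default = PipelineConfig().to_dict()
        mine = self.to_dict()
        return {k: v for k, v in mine.items() if default.get(k) != v}


def _region_seed(seed: int, i: int, salt: int = 0) -> int:
    return int((seed * 10007 + i * 131 + salt) % (2**31 - 1))


def concat_neurons(a: SpikeDataset, b: SpikeDataset) -> SpikeDataset:
    """Merge two datasets recorded on the same trials into one."""
    neurons_b = b.neurons.copy()
    neurons_b["neuron_id"] = neurons_b["neuron_id"] + a.n_neurons
    return SpikeDataset(
        spikes=a.spikes + b.spikes,
        trials=a.trials,
        neurons=pd.concat([a.neurons, neurons_b], ignore_index=True),
        ground_truth={"a": a.ground_truth, "b": b.ground_truth},
    )


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict[str, SpikeDataset]:
    """Generate one accumulator-driven dataset per synthetic region."""
    datasets = {}
    for i, region in enumerate(cfg.regions):
        seed = _region_seed(cfg.seed, i)
        trials = make_task_trials(region.n_trials, seed=seed)
        spec = acc.build_accumulator(
            region.kind,
            init_values={
                "A_acc": region.A_acc, "V_acc": region.V_acc, "Q_acc": region.Q_acc
            },
            n_neurons=region.n_neurons,
            dt=cfg.fit_dt,
            seed=seed,
        )
        ds = simulate_accumulator_dataset(
            spec, trials, seed=seed + 1, onset_delay=cfg.onset_delay
        )
        if region.n_distractors > 0:
            distract = make_selectivity_cohort(
                region.n_distractors,
                tuning={"stimulus": 8.0},
                baseline_rate=8.0,
                trials=ds.trials,
                seed=seed + 2,
            )
            ds = concat_neurons(ds, distract)
        ds.neurons["region"] = region.name
        datasets[region.name] = ds
        write_dataset(ds, outdir / "data" / region.name)
        acc.save_spec(spec, outdir / "data" / region.name / "true_spec.yaml")
        log.info("simulated region %s: %d neurons, %d trials",
                 region.name, ds.n_neurons, len(ds.trials))
    return datasets


def _load_datasets(outdir: Path) -> dict[str, SpikeDataset]:
    out = {}
    for sub in sorted((outdir / "data").iterdir()):
        if sub.is_dir():
            out[sub.name] = read_dataset(sub)
    return out


def stage_dpca(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Demix + cluster neurons per region; writes clusters.csv."""
    rows = []
    for region, ds in _load_datasets(outdir).items():
        tensor = build_marginalized_tensor(ds, binsize=cfg.fit_dt)
        result = fit_dpca(tensor)
        idx = np.where(tensor.include)[0]
        pts = np.column_stack([result.r2_st, result.r2_dt])
        ok = np.all(np.isfinite(pts), axis=1)
        labels = cluster_neurons(pts[ok], seed=cfg.seed)
        labels.insert(0, "neuron_id", ds.neurons["neuron_id"].to_numpy()[idx[ok]])
        labels.insert(1, "region", region)
        rows.append(labels)
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(outdir / "clusters.csv", index=False)
    return table


def ramping_mask(
    dataset: SpikeDataset, window: tuple[float, float] = (0.0, 0.3),
    binsize: float = 0.01, alpha: float = 0.05,
) -> np.ndarray:
    """Automated ramping screen: significant trial-averaged rate slope over
    the accumulation window, with sign consistent with the neuron's choice
    preference (contra-preferring neurons ramp up on contralateral choices)."""
    counts, t = dataset.bin_counts(align="stim_onset", window=window, binsize=binsize)
    choice = dataset.trials["choice"].to_numpy()
    out = np.zeros(dataset.n_neurons, bool)
    for n in range(dataset.n_neurons):
        pref = dataset.neurons["pref_side"].iloc[n]
        mask = choice == ("right" if pref == "contra" else "left")
        if mask.sum() < 5:
            continue
        trace = np.nanmean(counts[mask, n, :], axis=0) / binsize
        res = stats.linregress(t, trace)
        out[n] = (res.pvalue < alpha) and (res.slope > 0)
    return out


def stage_selectivity(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """CP/ES shuffle significance + ramping screen; writes ddm_neurons.csv."""
    clusters = pd.read_csv(outdir / "clusters.csv")
    rows = []
    for region, ds in _load_datasets(outdir).items():
        cp = sel.shuffle_significance(
            ds, "CP", n_shuffles=cfg.n_shuffles, seed=_region_seed(cfg.seed, 0, 3)
        )
        es = sel.shuffle_significance(
            ds, "ES", n_shuffles=cfg.n_shuffles, seed=_region_seed(cfg.seed, 0, 4)
        )
        ramp = ramping_mask(ds)
        reg_clusters = clusters[clusters["region"] == region]
        decision_ids = set(
            reg_clusters.loc[reg_clusters["label"] == "decision", "neuron_id"]
        )
        for n in range(ds.n_neurons):
            nid = int(ds.neurons["neuron_id"].iloc[n])
            cp_sig = bool(cp.significant[n].any())
            es_sig = bool(es.significant[n].any())
            in_decision = nid in decision_ids
            # Synthetic accumulator neurons are evidence-driven, hence
            # strongly stimulus-coupled; the (R2_st, R2_dt) clustering cannot
            # separate them from stimulus-only cells the way it separates
            # mixed real populations.  Significant choice probability is the
            # decision-coding gate; cluster membership is reported alongside.
            rows.append(
                {
                    "neuron_id": nid,
                    "region": region,
                    "pref_side": ds.neurons["pref_side"].iloc[n],
                    "decision_cluster": in_decision,
                    "cp_significant": cp_sig,
                    "es_significant": es_sig,
                    "ramping": bool(ramp[n]),
                    "ddm_like": cp_sig and es_sig and bool(ramp[n]),
                }
            )
        out = sel.SelectivityResult  # noqa: F841  (tables below)
        cp.to_frame().to_csv(outdir / f"selectivity_CP_{region}.csv", index=False)
        es.to_frame().to_csv(outdir / f"selectivity_ES_{region}.csv", index=False)
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "ddm_neurons.csv", index=False)
    return table


def form_subpopulations(
    ddm_neurons: pd.DataFrame,
    size: int = 4,
    n_per_region: int = 20,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sample subpopulations of DDM-like neurons without replacement.

    Each draw picks ``size`` neurons within a region; a subpopulation is
    bilateral when it contains both contralateral- and ipsilateral-preferring
    neurons, otherwise unilateral (fitted with the single accumulator only).
    Regions with fewer than ``size`` DDM-like neurons are skipped.
    """
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for region, grp in ddm_neurons[ddm_neurons["ddm_like"]].groupby("region"):
        ids = grp["neuron_id"].to_numpy()
        sides = grp["pref_side"].to_numpy()
        if len(ids) < size:
            log.warning("region %s skipped: %d < %d DDM-like neurons",
                        region, len(ids), size)
            continue
        for _ in range(n_per_region):
            pick = rng.choice(len(ids), size=size, replace=False)
            bilateral = len(set(sides[pick])) == 2
            rows.append(
                {
                    "subpop_id": sid,
                    "region": region,
                    "neuron_ids": ",".join(map(str, ids[pick])),
                    "bilateral": bilateral,
                }
            )
            sid += 1
    return pd.DataFrame(rows)


def _subset_dataset(ds: SpikeDataset, neuron_ids: list[int]) -> SpikeDataset:
    idx = [int(np.where(ds.neurons["neuron_id"] == nid)[0][0]) for nid in neuron_ids]
    return SpikeDataset(
        spikes=[ds.spikes[i] for i in idx],
        trials=ds.trials,
        neurons=ds.neurons.iloc[idx].reset_index(drop=True),
        ground_truth={},
    )


def stage_fit(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Fit candidate accumulators to every subpopulation; writes fits.csv and
    one YAML spec per (subpopulation, model)."""
    ddm = pd.read_csv(outdir / "ddm_neurons.csv")
    subpops = form_subpopulations(
        ddm, size=cfg.subpop_size, n_per_region=cfg.n_subpops_per_region,
        seed=cfg.seed + 17,
    )
    subpops.to_csv(outdir / "subpopulations.csv", index=False)
    datasets = _load_datasets(outdir)
    (outdir / "fits").mkdir(exist_ok=True, parents=True)
    rows = []
    for row in subpops.itertuples():
        ds = _subset_dataset(
            datasets[row.region], [int(s) for s in row.neuron_ids.split(",")]
        )
        kinds = (
            ("single", "independent_race", "dependent_race")
            if row.bilateral
            else ("single",)
        )
        for kind in kinds:
            fit = fit_laplace_em(
                ds, kind,
                init_grid=cfg.init_grid,
                latency=cfg.latency,
                n_em=cfg.n_em,
                dt=cfg.fit_dt,
                rt_range=cfg.rt_range,
            )
            score = ms.aic(fit, n_samples=cfg.aic_samples,
                           seed=_region_seed(cfg.seed, row.subpop_id, 5))
            acc.save_spec(fit.spec, outdir / "fits" / f"sub{row.subpop_id}_{kind}.yaml")
            rows.append(
                {
                    "subpop_id": row.subpop_id,
                    "region": row.region,
                    "bilateral": row.bilateral,
                    "model": kind,
                    "aic": score.aic,
                    "k": score.k,
                    "expected_loglik": score.expected_loglik,
                    "mc_se": score.mc_se,
                    "converged": fit.converged,
                    "A_acc": ts.recurrent_strength(fit.spec),
                }
            )
            log.info("fit subpop %d %s: AIC=%.1f", row.subpop_id, kind, score.aic)
    columns = ["subpop_id", "region", "bilateral", "model", "aic", "k",
               "expected_loglik", "mc_se", "converged", "A_acc"]
    table = pd.DataFrame(rows, columns=columns)
    table.to_csv(outdir / "fits.csv", index=False)
    return table


def stage_compare(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """AIC-difference verdict per subpopulation; writes comparison.csv."""
    fits = pd.read_csv(outdir / "fits.csv")
    rows = []
    for sid, grp in fits.groupby("subpop_id"):
        scores = [
            ms.ModelScore(
                model=r.model, aic=r.aic, k=int(r.k),
                expected_loglik=r.expected_loglik, mc_se=r.mc_se, n_samples=0,
            )
            for r in grp.itertuples()
        ]
        verdict = ms.compare_models(scores, threshold=cfg.aic_threshold)
        row = {
            "subpop_id": sid,
            "region": grp["region"].iloc[0],
            "bilateral": grp["bilateral"].iloc[0],
            "preferred": verdict.preferred or "excluded",
        }
        for m in ("single", "independent_race", "dependent_race"):
            row[f"AIC_{m}"] = grp.loc[grp["model"] == m, "aic"].squeeze() \
                if (grp["model"] == m).any() else np.nan
        row.update(verdict.pairwise)
        rows.append(row)
    table = pd.DataFrame(
        rows, columns=["subpop_id", "region", "bilateral", "preferred",
                       "AIC_single", "AIC_independent_race",
                       "AIC_dependent_race", "delta_si", "delta_sd",
                       "delta_id"],
    )
    table.to_csv(outdir / "comparison.csv", index=False)
    return table


def stage_timescales(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Timescales of preferred models; region hierarchy and strength
    correlations; writes timescales.csv, region_timescales.csv,
    pairwise_p.csv, strength_correlation.csv."""
    comparison = pd.read_csv(outdir / "comparison.csv")
    rows = []
    curves_by_region: dict[str, list] = {}
    rng = np.random.default_rng(cfg.seed + 23)
    for row in comparison.itertuples():
        model = row.preferred
        if model == "excluded":
            continue
        spec = acc.load_spec(outdir / "fits" / f"sub{row.subpop_id}_{model}.yaml")
        tau, sd, fits = ts.subpopulation_timescale(
            spec, n_samples=cfg.timescale_samples, n_trials=cfg.timescale_trials,
            delta=cfg.autocorr_delta, seed=int(rng.integers(2**31 - 1)),
        )
        counts = ts.simulate_fixed_length_counts(
            spec, cfg.timescale_trials, delta=cfg.autocorr_delta,
            rng=np.random.default_rng(int(rng.integers(2**31 - 1))),
        )
        curve = ts.spike_count_autocorrelation(counts, delta=cfg.autocorr_delta)
        curves_by_region.setdefault(row.region, []).append(curve)
        rows.append(
            {
                "subpop_id": row.subpop_id,
                "region": row.region,
                "model": model,
                "tau": tau,
                "tau_sd": sd,
                "strength": ts.recurrent_strength(spec),
            }
        )
    table = pd.DataFrame(
        rows, columns=["subpop_id", "region", "model", "tau", "tau_sd", "strength"]
    )
    table.to_csv(outdir / "timescales.csv", index=False)
    if curves_by_region:
        taus_by_region = {
            r: grp["tau"].to_numpy() for r, grp in table.groupby("region")
        }
        result = ts.population_timescale(
            curves_by_region, n_boot=cfg.n_boot, seed=cfg.seed + 29,
            subpop_taus=taus_by_region,
        )
        result.table.to_csv(outdir / "region_timescales.csv", index=False)
        result.pairwise_p.to_csv(outdir / "pairwise_p.csv")
    if len(table):
        corr = ts.strength_timescale_correlation(table)
        corr.to_csv(outdir / "strength_correlation.csv", index=False)
    return table


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "dpca": stage_dpca,
    "selectivity": stage_selectivity,
    "fit": stage_fit,
    "compare": stage_compare,
    "timescales": stage_timescales,
}


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the configured stages in order and write a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = {}
    for stage in cfg.stages:
        if stage not in STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        log.info("running stage %s", stage)
        results[stage] = STAGE_FUNCS[stage](cfg, outdir)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "overrides": cfg.overrides(),
        "config": cfg.to_dict(),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return results
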