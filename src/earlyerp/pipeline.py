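"""End-to-end orchestration: simulate -> preprocess -> detect -> peaks/WOIs
-> amplitudes -> spatial PCA -> contrasts -> peak-to-peak decomposition.

A run is fully determined by its :class:`RunConfig` (including the master
seed); per-participant randomness uses child streams derived from it.
Scaled-down runs (fewer trials per condition) keep the sampling law of the
per-condition averages by shrinking the stochastic background in
proportion (see :func:`earlyerp.simulate.scaled_params`).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import components as comp
from . import preprocess as prep
from . import spca as sp
from . import stats as st

from .layout import build_adjacency, make_layout
from .simulate import (
    SimParams,
    default_templates,
    design_sequence,
    scaled_params,
    simulate_recording,
)

FULL_TRIALS = {1: 200, 2: 500}
MIN_TRIALS = {1: 150, 2: 400}
SEARCH_WINDOWS = {
    "N40": (30.0, 60.0),
    "P80": (60.0, 110.0),
    "P100": (70.0, 130.0),
}
#: contralateral meta/selection side by stimulated visual hemifield
CONTRA_SIDE = {"FIX": "bilateral", "UL": "right", "LL": "right", "UR": "left", "LR": "left"}


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    experiment: int = 1
    n_participants: int = 36
    trials_per_condition: int | None = None  # None -> design default
    variance_preserving: bool = True         # scale noise when trials reduced
    locations: tuple | None = None           # None -> all design locations
    category_effect_ptp: float = 1.2
    participant_effect_sd: float = 1.0
    seed: int = 0
    # preprocessing
    filter_low: float = 0.01
    filter_high: float = 30.0
    lag_ms: float = 8.0
    abs_limit_uv: float = 100.0
    sd_mult: float = 3.5
    min_trials: int | None = None            # None -> scaled design default
    blink_method: str = "regression"
    blink_rate: float = 8.0
    # analysis
    association: str = "correlation"
    k_factors: int | str = "scree"
    alpha: float = 0.05
    out_dir: str | None = None

    def sim_params(self) -> SimParams:
        full = FULL_TRIALS[self.experiment]
        params = SimParams(
            n_participants=self.n_participants,
            component_templates=default_templates(self.experiment),
            category_effect_ptp=self.category_effect_ptp,
            participant_effect_sd=self.participant_effect_sd,
            alpha_phase_locked=(self.experiment == 1),
            blink_rate=self.blink_rate,
            trigger_lag_ms=self.lag_ms,
            seed=self.seed,
        )
        npc = self.trials_per_condition
        if npc is not None and self.variance_preserving and npc < full:
            params = scaled_params(params, full, npc)
        return params

    def effective_min_trials(self) -> int:
        if self.min_trials is not None:
            return self.min_trials
        full = FULL_TRIALS[self.experiment]
        npc = self.trials_per_condition or full
        # keep the design's rejection headroom: 150/200 and 400/500
        return int(round(MIN_TRIALS[self.experiment] * npc / full))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunReport:
    experiment: int
    detection: dict            # (category, location) -> bool
    peaks: dict                # (component, location) -> ms
    wois: dict                 # (component, location) -> (lo, hi)
    spca_summary: dict         # key -> {'k': int, 'explained_pct': float}
    contrasts: dict            # key -> ContrastResult
    ancova: st.AncovaResult | None
    alpha_adjusted: float
    kept_counts: pd.DataFrame
    included: pd.DataFrame
    truth: object
    seed: int
    config_hash: str

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="list")
            return str(o)

        payload = {
            "experiment": self.experiment,
            "detection": {f"{c}/{l}": bool(v) for (c, l), v in self.detection.items()},
            "peaks": {f"{c}@{l}": v for (c, l), v in self.peaks.items()},
            "wois": {f"{c}@{l}": v for (c, l), v in self.wois.items()},
            "spca": self.spca_summary,
            "contrasts": {k: dataclasses.asdict(v) for k, v in self.contrasts.items()},
            "ancova": dataclasses.asdict(self.ancova) if self.ancova else None,
            "alpha_adjusted": self.alpha_adjusted,
            "seed": self.seed,
            "config_hash": self.config_hash,
        }
        return json.dumps(payload, indent=2, default=enc, sort_keys=True)


def _combine_averages(avg_sets: list[comp.AverageSet]) -> comp.AverageSet:
    part = {}
    for a in avg_sets:
        part.update(a.participant_averages)
    grand = {}
    for cat, loc in sorted({(c, l) for (_, c, l) in part}):
        grand[(cat, loc)] = np.mean(
            [w for (p, c, l), w in part.items() if (c, l) == (cat, loc)], axis=0
        )
    a0 = avg_sets[0]
    return comp.AverageSet(
        participant_averages=part, grand=grand, times=a0.times, channel_names=a0.channel_names
    )


def _scores_by_condition(model: sp.SpatialFactorModel, factor: int) -> tuple[np.ndarray, np.ndarray, list]:
    """Pivot factor scores to aligned (spider, wheel) participant vectors."""
    df = pd.DataFrame(
        {"score": model.scores[:, factor]}, index=model.case_index
    ).reset_index()
    wide = df.pivot(index="participant", columns="category", values="score")
    return wide["spider"].to_numpy(), wide["wheel"].to_numpy(), list(wide.index)


def run_experiment(config: RunConfig) -> RunReport:
    """Execute the full replication pipeline on synthetic data."""
    if config.experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    layout = make_layout()
    params = config.sim_params()
    npc = config.trials_per_condition

    # --- simulate + preprocess per participant -----------------------------
    avg_sets = []
    reports = []
    ss = np.random.SeedSequence([config.seed, config.experiment])
    child_seeds = ss.generate_state(config.n_participants) % (2**31 - 1)
    for p in range(config.n_participants):
        plan = design_sequence(
            config.experiment, int(child_seeds[p]),
            trials_per_condition=npc, locations=config.locations,
        )
        rec, truth = simulate_recording(plan, layout, params, participant=p)
        es, rep = prep.preprocess_recording(
            rec,
            layout,
            low=config.filter_low,
            high=config.filter_high,
            lag_ms=config.lag_ms,
            blink_method=config.blink_method,
            abs_limit=config.abs_limit_uv,
            sd_mult=config.sd_mult,
        )
        reports.append(rep)
        avg_sets.append(comp.grand_average(es, scalp_names=layout.names))

    counts = pd.concat([r.kept_counts() for r in reports], ignore_index=True)
    included = prep.enforce_min_trials(counts, config.effective_min_trials())
    good = set(included.loc[included["included"], "participant"])
    avg_sets = [
        a for a in avg_sets if set(p for (p, _, _) in a.participant_averages) <= good
    ]
    if not avg_sets:
        raise RuntimeError("all participants excluded by the minimum-trial rule")
    avgs = _combine_averages(avg_sets)

    locations = sorted({l for (_, l) in avgs.grand}, key=lambda s: (s != "FIX", s))
    pos_name = "P80" if config.experiment == 1 else "P100"
    neg_spec = comp.ComponentSpec("N40", "negative", SEARCH_WINDOWS["N40"])
    pos_spec = comp.ComponentSpec(pos_name, "positive", SEARCH_WINDOWS[pos_name])
    adjacency = build_adjacency(layout)
    crit = comp.DetectionCriterion()

    detection = {}
    for (cat, loc), wave in avgs.grand.items():
        detection[(cat, loc)] = comp.detect_component(
            wave, avgs.times, neg_spec, crit, adjacency, layout
        ).detected

    peaks, wois, tables = {}, {}, {}
    for loc in locations:
        electrodes = comp.default_meta_electrodes(layout, CONTRA_SIDE[loc])
        meta = comp.meta_average(avgs.grand, layout, avgs.channel_names, electrodes, loc)
        for spec in (neg_spec, pos_spec):
            peak = comp.find_peak(meta, avgs.times, spec)
            woi = comp.make_woi(peak, spec)
            peaks[(spec.name, loc)] = peak
            wois[(spec.name, loc)] = (woi.lo, woi.hi)
            tables[(spec.name, loc)] = comp.mean_amplitude(avgs, woi, loc)
    ptp_table = comp.peak_to_peak(tables[(pos_name, "FIX")], tables[("N40", "FIX")])
    tables[("PTP", "FIX")] = ptp_table

    # --- spatial PCA + contrasts -------------------------------------------
    contrast_plan = [("N40", "FIX", "less")]
    contrast_plan += [(pos_name, loc, "greater") for loc in locations]
    contrast_plan += [("PTP", "FIX", "greater")]

    spca_summary, contrasts, models = {}, {}, {}
    for name, loc, direction in contrast_plan:
        mat, case_index = sp.build_case_matrix(tables[(name, loc)])
        model = sp.fit_spca(
            mat, case_index, avgs.channel_names, k=config.k_factors,
            association=config.association,
        )
        factor = sp.select_posterior_factor(model, layout, laterality=CONTRA_SIDE[loc])
        x, y, _ = _scores_by_condition(model, factor)
        key = f"{name}@{loc}"
        models[key] = (model, factor)
        spca_summary[key] = {
            "k": model.k,
            "explained_pct": model.explained_variance_pct,
            "factor": factor,
        }
        contrasts[key] = st.paired_t_one_tailed(x, y, direction=direction)

    n_pos_contrasts = sum(1 for n, _, _ in contrast_plan if n == pos_name)
    alpha_adj = st.bonferroni_alpha(config.alpha, n_pos_contrasts)

    # --- peak-to-peak decomposition ----------------------------------------
    ancova = None
    mk, fk = models[f"PTP@FIX"]
    mn, fn = models["N40@FIX"]
    mp, fp = models[f"{pos_name}@FIX"]
    sx, sy, parts = _scores_by_condition(mk, fk)
    nx, ny, _ = _scores_by_condition(mn, fn)
    px, py, _ = _scores_by_condition(mp, fp)
    ancova = st.ptp_decomposition(
        ptp_scores=np.concatenate([sx, sy]),
        n_amp=np.concatenate([nx, ny]),
        p_amp=np.concatenate([px, py]),
        condition=np.array(["spider"] * len(sx) + ["wheel"] * len(sy)),
        participant=np.array(parts + parts),
    )

    report = RunReport(
        experiment=config.experiment,
        detection=detection,
        peaks=peaks,
        wois=wois,
        spca_summary=spca_summary,
        contrasts=contrasts,
        ancova=ancova,
        alpha_adjusted=alpha_adj,
        kept_counts=counts,
        included=included,
        truth=make_truth_for(config),
        seed=config.seed,
        config_hash=config.config_hash(),
    )
    if config.out_dir:
        _write_outputs(config, report, tables, models)
    return report


def make_truth_for(config: RunConfig):
    from .simulate import make_truth

    return make_truth(config.sim_params())


def _write_outputs(config: RunConfig, report: RunReport, tables: dict, models: dict) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={report.config_hash} seed={report.seed}\n"
    for (name, loc), table in tables.items():
        path = out / f"amplitudes_{name}_{loc}.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            table.to_csv(fh, sep="\t")
    for key, (model, factor) in models.items():
        sp.export_model(model, out / f"spca_{key.replace('@', '_')}")
    rows = []
    for key, c in report.contrasts.items():
        rows.append(
            {
                "contrast": key,
                "t": c.t,
                "df": c.df,
                "p_one_tailed": c.p_one_tailed,
                "cohen_d": c.cohen_d,
                "bf10": c.bf10,
                "direction": c.direction,
                "alpha_adjusted": report.alpha_adjusted,
                "significant": c.p_one_tailed < report.alpha_adjusted,
            }
        )
    with open(out / "contrasts.tsv", "w") as fh:
        fh.write(header)
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
    with open(out / "run_report.json", "w") as fh:
        fh.write(report.to_json())


# ---------------------------------------------------------------------------
# analytic acceptance suite
# ---------------------------------------------------------------------------

def acceptance_suite() -> pd.DataFrame:
    """Recompute every analytic target from its printed inputs.

    Cohen's d identities (d = t/sqrt(n)), one-sided default-prior Bayes
    factors by quadrature, the Bonferroni alpha, WOI reconstruction from
    printed peaks, and the design arithmetic of the trial plans.
    Returns a table with one row per check and a ``passed`` column.
    """
    from . import reference as ref

    rows = []
    for label, t, n, direction, d_printed, bf_printed in ref.REFERENCE_CONTRASTS:
        d = t / np.sqrt(n)
        rows.append(
            {
                "check": f"d_identity:{label}",
                "value": round(d, 3),
                "expected": d_printed,
                "passed": bool(abs(round(d, 3) - d_printed) <= 0.0015),
            }
        )
        bf = st.jzs_bf_one_sided(t, n, r=0.707, direction=direction)
        tol = 0.02 if abs(t) < 1.0 else 0.01
        rows.append(
            {
                "check": f"bf10:{label}",
                "value": bf,
                "expected": bf_printed,
                "passed": bool(abs(bf - bf_printed) / bf_printed <= tol),
            }
        )
    for label, polarity, peak, lo, hi in ref.REFERENCE_WOIS:
        spec = comp.ComponentSpec(label, polarity, (0.0, 200.0))
        woi = comp.make_woi(peak, spec)
        rows.append(
            {
                "check": f"woi:{label}",
                "value": (woi.lo, woi.hi),
                "expected": (lo, hi),
                "passed": bool(woi.lo == lo and woi.hi == hi),
            }
        )
    rows.append(
        {
            "check": "bonferroni",
            "value": st.bonferroni_alpha(0.05, ref.BONFERRONI_CONTRASTS),
            "expected": ref.BONFERRONI_ALPHA,
            "passed": st.bonferroni_alpha(0.05, ref.BONFERRONI_CONTRASTS) == ref.BONFERRONI_ALPHA,
        }
    )
    plan = design_sequence(1, seed=0)
    rows.append(
        {"check": "design_exp1_total_trials", "value": len(plan), "expected": 2000,
         "passed": len(plan) == 2000}
    )
    plan2 = design_sequence(2, seed=0)
    rows.append(
        {"check": "design_exp2_total_trials", "value": len(plan2), "expected": 1000,
         "passed": len(plan2) == 1000}
    )
    return pd.DataFrame(rows)
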