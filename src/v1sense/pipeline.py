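"""End-to-end orchestration: simulate → extract → analyze → report.

``run_pipeline`` runs the full desk-scale study on synthetic data: a
stimulus session (responsiveness, NAI), a spontaneous session
(n-order synchrony vs its shuffle null, pairwise correlation vs
distance, NND dispersion of the four functional types), the vidget
behavioral session, and a batch of random dendritic trees (DC).  Every
random stage consumes its own sub-seed derived from the master seed, so
a fixed config reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as vio
from . import morpho, pairwise, spatial, sync, synthgen, traces, vidget
from .protocol import StimulusProtocol

log = logging.getLogger("v1sense")

STAGES = (
    "protocol",
    "population",
    "stimulus_session",
    "spontaneous_session",
    "vidget_session",
    "morphology",
)


@dataclass
class RunConfig:
    """Parameters of one pipeline run (defaults: wild-type-like demo)."""

    seed: int = 0
    n_neurons: int = 50
    fov_um: float = synthgen.FOV_UM
    p_resp: dict = field(default_factory=lambda: {"S1": 0.10, "S4": 0.35})
    repeats: int = 5
    # imaging
    f_hz: float = 20.4
    tau_decay_s: float = 1.0
    amp_dff: float = 0.1
    noise_sd_dff: float = 0.02
    bg_rate_hz: float = 0.05
    spont_T_s: float = 73.5
    spont_bg_rate_hz: float = 0.1
    sync_rate_hz: float = 0.0
    sync_recruit: float = 0.5
    baseline_mode: str = "global-median"
    k_sd: float = 2.5
    # sync
    N_subgroup: int = 30
    n_shuffles: int = 1000
    # pairwise
    bin_um: float = 50.0
    # spatial
    nnd_k: int = 5
    nnd_tol: float = 1e-3
    # vidget
    vidget_amp: dict = field(default_factory=lambda: {"S1": 0.3, "S4": 0.6})
    vidget_latency_s: float = 0.1
    vidget_noise_sd: float = 0.01
    # morphology
    n_trees: int = 10
    branch_prob: float = 0.5
    outdir: str | None = None

    def validate(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be >= 2")
        if not self.p_resp:
            raise ValueError("p_resp must name at least one stimulus")
        for lab, p in self.p_resp.items():
            if not 0 <= p <= 1:
                raise ValueError(f"p_resp[{lab}] outside [0, 1]")
        if self.n_shuffles < 1 or self.N_subgroup < 2:
            raise ValueError("invalid sync parameters")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sub_rngs(seed: int, n: int = 8):
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run all stages; return (and optionally write) the summary report."""
    config.validate()
    outdir = Path(outdir) if outdir else (Path(config.outdir) if config.outdir else None)
    rngs = _sub_rngs(config.seed)
    summary: dict = {"seed": config.seed, "n_neurons": config.n_neurons}

    stage = "protocol"
    try:
        protocol = StimulusProtocol.generate(
            repeats=config.repeats,
            labels=tuple(sorted(config.p_resp)),
            seed=rngs[0],
        )

        stage = "population"
        pop = synthgen.make_uniform_population(
            config.n_neurons,
            p_resp=config.p_resp,
            fov_um=config.fov_um,
            seed=rngs[1],
        )

        stage = "stimulus_session"
        cfg_stim = synthgen.SimConfig(
            f=config.f_hz,
            T=protocol.span,
            tau_decay=config.tau_decay_s,
            amp=config.amp_dff,
            noise_sd=config.noise_sd_dff,
            bg_rate=config.bg_rate_hz,
        )
        truth = synthgen.simulate_activity(pop, protocol, cfg_stim, seed=rngs[2])
        ts = synthgen.render_traces(truth, cfg_stim, positions=pop.positions, seed=rngs[2])
        ts = traces.compute_dff(ts, baseline_mode=config.baseline_mode, protocol=protocol)
        events = traces.detect_transients(ts, k_sd=config.k_sd)
        table = traces.classify_responsive(events, protocol)
        traces.response_amplitude(ts, protocol, table)
        labels = list(table.labels)
        summary["responsiveness"] = {
            "percent_responsive": {
                lab: table.percent_responsive(lab) for lab in labels
            },
            "mean_probability": {
                lab: float(table.probability[lab].mean()) for lab in labels
            },
            "mean_amplitude": {
                lab: float(np.nanmean(table.amplitude[lab])) for lab in labels
            },
        }
        summary["nai"] = (
            table.nai() if {"S1", "S4"} <= set(labels) else None
        )

        stage = "spontaneous_session"
        cfg_spont = synthgen.SimConfig(
            f=config.f_hz,
            T=config.spont_T_s,
            tau_decay=config.tau_decay_s,
            amp=config.amp_dff,
            noise_sd=config.noise_sd_dff,
            bg_rate=config.spont_bg_rate_hz,
            sync_rate=config.sync_rate_hz,
            sync_recruit=config.sync_recruit,
        )
        truth_sp = synthgen.simulate_activity(pop, None, cfg_spont, seed=rngs[3])
        ts_sp = synthgen.render_traces(
            truth_sp, cfg_spont, positions=pop.positions, seed=rngs[3]
        )
        ts_sp = traces.compute_dff(ts_sp, baseline_mode="global-median")
        ev_sp = traces.detect_transients(ts_sp, k_sd=config.k_sd)
        N = min(config.N_subgroup, ev_sp.n_neurons)
        sub = sync.subsample_circuit(ev_sp, N=N, seed=rngs[4])
        obs = sync.observed_sync(sub)
        null = sync.shuffle_null(sub, n_shuffles=config.n_shuffles, seed=rngs[4])
        obs_ranges = sync.aggregate_ranges(obs.probs)
        summary["sync"] = {
            "N": N,
            "total_n": obs.total_n,
            "range_probs": {"1-10": obs_ranges[0], "11-inf": obs_ranges[1]},
            "null_mean": dict(
                zip(("1-10", "11-inf"), sync.aggregate_ranges(null.mean()))
            ),
            "null_p97_5": dict(zip(("1-10", "11-inf"), null.range_percentile(97.5))),
        }

        dff_proc = pairwise.preprocess_traces(ts_sp.dff, ts_sp.f)
        dc = pairwise.distance_binned_correlation(
            dff_proc, pop.positions, bin_um=config.bin_um
        )
        valid = ~np.isnan(dc.coefficients)
        summary["pairwise"] = {
            "bin_um": config.bin_um,
            "bin_mean": [None if np.isnan(v) else float(v) for v in dc.bin_mean],
            "n_pairs": int(valid.sum()),
            "overall_mean": float(dc.coefficients[valid].mean()) if valid.any() else None,
        }

        stage = "spontaneous_session"
        types = spatial.assign_types(table) if {"S1", "S4"} <= set(labels) else None
        if types is not None and config.n_neurons > config.nnd_k:
            nnd = spatial.knn_subgroup_nnd(
                pop.positions,
                group_ids=types,
                k=config.nnd_k,
                tol=config.nnd_tol,
                seed=rngs[5],
            )
            summary["nnd"] = {
                "k": config.nnd_k,
                "dispersion_um": {
                    spatial.TYPE_LABELS.get(int(g), str(g)): v
                    for g, v in nnd.group_dispersion.items()
                },
            }
        else:
            summary["nnd"] = None

        stage = "vidget_session"
        piezo = synthgen.simulate_piezo(
            protocol,
            evoked_amp=config.vidget_amp,
            latency_s=config.vidget_latency_s,
            noise_sd=config.vidget_noise_sd,
            seed=rngs[6],
        )
        vres = vidget.analyze_vidget(piezo, protocol)
        summary["vidget"] = {
            "score": vres.score_by_label(protocol),
            "mean_delay_s": {
                lab: float(np.nanmean(vres.delays[np.asarray(protocol.labels) == lab]))
                for lab in protocol.stimulus_labels
            },
            "k_baseline": vres.k_baseline,
            "k_stimulus": vres.k_stimulus,
        }

        stage = "morphology"
        tree_rngs = np.random.SeedSequence(config.seed).spawn(8)[7].spawn(config.n_trees)
        trees = [
            synthgen.make_morphology(
                branch_prob=config.branch_prob, seed=np.random.default_rng(s)
            )
            for s in tree_rngs
        ]
        mtab = morpho.metrics_table(trees)
        summary["morpho"] = {
            "n_trees": config.n_trees,
            "means": {col: float(mtab[col].mean()) for col in mtab.columns},
        }
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc

    summary = _roundtrip_floats(summary)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        protocol.to_yaml(outdir / "protocol.yaml")
        vio.write_traces_csv(outdir / "traces_stimulus.csv", ts)
        vio.write_events_csv(outdir / "events_spontaneous.csv", ev_sp)
        vio.write_piezo_csv(outdir / "piezo.csv", piezo)
        table.probability.to_csv(outdir / "response_probability.tsv", sep="\t")
        mtab.to_csv(outdir / "morpho_metrics.tsv", sep="\t", index=False)
        dc.table().to_csv(outdir / "pairwise_distance_bins.tsv", sep="\t", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        log.info("pipeline outputs written to %s", outdir)
    return summary


def _roundtrip_floats(obj):
    """Coerce numpy scalars to plain floats/ints for stable JSON."""
    if isinstance(obj, dict):
        return {k: _roundtrip_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_roundtrip_floats(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj
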