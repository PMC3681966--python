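"""End-to-end orchestration: simulate → preprocess → tfr → sync → stats → classify.

A single YAML/dict config drives the run; every stage writes its outputs
under ``out_dir`` and the run manifest records the config snapshot, the
per-stage seeds, output hashes and trial counts, so a rerun with the same
config reproduces identical files.  Seeds are mandatory: there is no
implicit global randomness.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import io as _io
from . import preprocess as _pre
from . import simulate as _sim
from . import stats as _stats
from . import synchrony as _sync
from . import timefreq as _tf
from .containers import InvariantError

KNOWN_STAGES = ("simulate", "preprocess", "tfr", "sync", "stats", "classify")


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int]
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    counts: dict[str, dict] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def save(self, path):
        with open(path, "w") as f:
            json.dump(self.__dict__, f, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _validate_config(cfg: dict) -> None:
    bad = []
    if "seed" not in cfg:
        bad.append("seed (mandatory)")
    if "out_dir" not in cfg:
        bad.append("out_dir (mandatory)")
    for st in cfg.get("stages", []):
        if st not in KNOWN_STAGES:
            bad.append(f"stages: unknown stage {st!r}")
    if bad:
        raise InvariantError("config schema violation: " + "; ".join(bad))


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as f:
            cfg = yaml.safe_load(f)
    _validate_config(cfg)
    return cfg


# ---------------------------------------------------------------------------
# Figure-data export (tabular text)
# ---------------------------------------------------------------------------

def export_tfr_matrix(path, freqs, times, matrix) -> None:
    """freqs × times matrix as TSV with a time header row and freq column."""
    df = pd.DataFrame(matrix, index=np.asarray(freqs),
                      columns=np.asarray(times))
    df.index.name = "freq_hz"
    df.to_csv(path, sep="\t")


def import_tfr_matrix(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return (df.index.to_numpy(float), df.columns.to_numpy(float),
            df.to_numpy(float))


def export_topography(path, labels, positions, values: dict) -> None:
    """Per-channel band values with montage coordinates."""
    cols = {"label": list(labels),
            "x": np.asarray(positions)[:, 0], "y": np.asarray(positions)[:, 1]}
    cols.update({k: np.asarray(v) for k, v in values.items()})
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def export_connectivity(path, labels, matrix) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=list(labels),
                      columns=list(labels))
    df.index.name = "channel"
    df.to_csv(path, sep="\t")


def import_connectivity(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), df.to_numpy(float)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config) -> RunManifest:
    """Execute the requested stages in order; halt on the first error.

    Returns the run manifest (also written to ``out_dir/manifest.json``).
    """
    cfg = load_config(config)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", list(KNOWN_STAGES))
    master = np.random.default_rng(int(cfg["seed"]))
    seeds = {st: int(master.integers(2 ** 31)) for st in KNOWN_STAGES}
    man = RunManifest(config=cfg, seeds=seeds, started=time.time())
    paradigm = cfg.get("paradigm", "rotation")

    def _register(path: Path):
        man.outputs[str(path)] = _sha256(path)

    rec = events = behaviour = None
    ep_analysis = ep_features = None
    tfr_analysis = tfr_features = None

    if "simulate" in stages:
        sim_cfg = _sim.SynthConfig(
            paradigm=paradigm, seed=seeds["simulate"],
            **cfg.get("simulate", {}))
        rec, events, behaviour, truth = _sim.generate_dataset(
            sim_cfg, return_truth=True)
        _io.write_recording(rec, out / "recording.h5", "container")
        _io.write_events(events, out / "events.csv")
        _io.write_behaviour(behaviour, out / "behaviour.csv")
        with open(out / "ground_truth.json", "w") as f:
            json.dump(truth, f, indent=2)
        for p in ("recording.h5", "events.csv", "behaviour.csv",
                  "ground_truth.json"):
            _register(out / p)
        man.counts["simulate"] = {"n_trials": sim_cfg.n_trials,
                                  "n_channels": rec.n_channels}

    if "preprocess" in stages:
        if rec is None:
            rec = _io.read_recording(out / "recording.h5")
            behaviour = _io.read_behaviour(out / "behaviour.csv")
        pcfg = _pre.PreprocConfig(
            epoch_window=(-0.2, 0.8) if paradigm == "rsvp" else (-1.5, 0.5),
            **cfg.get("preprocess", {}))
        ep_analysis = _pre.preprocess_recording(rec, paradigm, pcfg, behaviour)
        _io.save_epochs(ep_analysis, out / "epochs_analysis.h5")
        _register(out / "epochs_analysis.h5")
        man.counts["preprocess"] = {"n_trials": ep_analysis.n_trials,
                                    "provenance": ep_analysis.provenance}
        if paradigm == "rotation":
            ep_features = _pre.preprocess_recording(rec, paradigm, pcfg, behaviour,
                                          epoch_kind="movie_end")
            _io.save_epochs(ep_features, out / "epochs_features.h5")
            _register(out / "epochs_features.h5")

    if "tfr" in stages:
        if ep_analysis is None:
            ep_analysis = _io.load_epochs(out / "epochs_analysis.h5")
            if (out / "epochs_features.h5").exists():
                ep_features = _io.load_epochs(out / "epochs_features.h5")
        tcfg = cfg.get("tfr", {})
        freqs = np.arange(tcfg.get("fmin", 15), tcfg.get("fmax", 90) + 1,
                          tcfg.get("fstep", 1), dtype=float)
        decim = int(tcfg.get("decim", 10))
        tfr_analysis = _tf.tfr_decompose(ep_analysis, freqs, decim=decim)
        # perception maps are z-scored against the no-perception state
        unp = tfr_analysis.trial_mask("unperceived")
        if unp.any() and (~unp).any():
            tfr_analysis = _tf.normalize_to_reference(
                tfr_analysis, tfr_analysis.subset(unp))
        else:
            t0 = float(ep_analysis.tmin)
            tfr_analysis = _tf.baseline_normalize(
                tfr_analysis, tuple(tcfg.get("baseline", (t0, t0 + 0.5))))
        _io.save_tfr(tfr_analysis, out / "tfr_analysis.h5")
        _register(out / "tfr_analysis.h5")
        man.counts["tfr"] = {"clip_fraction": tfr_analysis.clip_fraction}
        if ep_features is not None:
            tfr_features = _tf.tfr_decompose(ep_features, freqs, decim=decim,
                                             compute_phase=False)
            t0 = float(ep_features.tmin)
            tfr_features = _tf.baseline_normalize(tfr_features, (t0, t0 + 0.5))
            _io.save_tfr(tfr_features, out / "tfr_features.h5")
            _register(out / "tfr_features.h5")
        # figure data: condition-average band maps
        avg = tfr_analysis.power.mean(axis=(0, 1))
        export_tfr_matrix(out / "tfr_grand_average.tsv",
                          tfr_analysis.freqs, tfr_analysis.times, avg)
        _register(out / "tfr_grand_average.tsv")

    if "sync" in stages:
        if tfr_analysis is None:
            tfr_analysis = _io.load_tfr(out / "tfr_analysis.h5")
        scfg = cfg.get("sync", {})
        window = tuple(scfg.get("window", (-1.0, 0.0)))
        m = _sync.imcoh_all_pairs(tfr_analysis)
        summary = _sync.connectivity_summary(m, time_window=window)
        for band in summary.band_names:
            export_connectivity(
                out / f"imcoh_{band}.tsv", summary.channel_labels,
                summary.matrix[band])
            _register(out / f"imcoh_{band}.tsv")
        if tfr_analysis.positions is not None:
            export_topography(
                out / "imcoh_topography.tsv", summary.channel_labels,
                tfr_analysis.positions,
                {band: summary.channel_mean[band]
                 for band in summary.band_names})
            _register(out / "imcoh_topography.tsv")
        man.counts["sync"] = {
            "n_pairs": len(m.pairs),
            "undefined_bins": int(np.isnan(m.values).sum()),
        }

    if "stats" in stages:
        if tfr_analysis is None:
            tfr_analysis = _io.load_tfr(out / "tfr_analysis.h5")
        stcfg = cfg.get("stats", {})
        window = tuple(stcfg.get("window", (-1.0, 0.0)))
        alpha = float(stcfg.get("alpha", 0.05))
        bands = _tf.BandSpec.default()
        banded = _tf.band_average(tfr_analysis, bands)
        tmask = ((tfr_analysis.times >= window[0])
                 & (tfr_analysis.times <= window[1]))
        perc = tfr_analysis.trial_mask("perceived")
        rows = []
        pvals, zs = [], []
        for name in bands.names():
            a = banded[name][~perc][:, tmask].mean(axis=1)  # no-perception
            b = banded[name][perc][:, tmask].mean(axis=1)   # perception
            z, p = _stats.rank_sum(a, b)
            pvals.append(p); zs.append(z)
        mask, p_adj = _stats.holm_correct(np.array(pvals), alpha)
        for i, name in enumerate(bands.names()):
            rows.append({"band": name, "z": zs[i], "p": pvals[i],
                         "p_holm": p_adj[i], "significant": bool(mask[i])})
        pd.DataFrame(rows).to_csv(out / "band_contrasts.tsv", sep="\t",
                                  index=False)
        _register(out / "band_contrasts.tsv")
        man.counts["stats"] = {"n_significant": int(mask.sum())}

    if "classify" in stages:
        if tfr_features is None:
            tfr_features = _io.load_tfr(out / "tfr_features.h5")
        if behaviour is None:
            behaviour = _io.read_behaviour(out / "behaviour.csv")
        ccfg = cfg.get("classify", {})
        band = ccfg.get("band", "60-75")
        window = tuple(ccfg.get("window", (-3.0, 0.0)))
        rts = np.array([behaviour.response_time_of(int(t))
                        for t in _io.load_epochs(
                            out / "epochs_features.h5").trial_ids]) \
            if (out / "epochs_features.h5").exists() else None
        fm = _classify.extract_features(
            tfr_features, band, window,
            response_times=rts, window_in_trial=tuple(
                ccfg.get("window_in_trial", (9.0, 12.0))))
        report = _classify.train_eval_cv(
            fm, k_folds=int(ccfg.get("folds", 3)),
            repetitions=int(ccfg.get("reps", 30)), seed=seeds["classify"])
        if int(ccfg.get("perms", 0)) >= 100:
            report.permutation_p = _classify.permutation_test(
                fm, n_permutations=int(ccfg["perms"]),
                seed=seeds["classify"] + 1)
        with open(out / "classifier_report.json", "w") as f:
            json.dump(report.as_dict(), f, indent=2)
        _register(out / "classifier_report.json")
        man.counts["classify"] = {
            "n_trials": len(fm.y), "n_excluded": len(fm.excluded_trials),
            "balanced_accuracy": report.balanced_accuracy,
        }

    man.finished = time.time()
    man.save(out / "manifest.json")
    return man


def verify_outputs(manifest_path) -> dict[str, bool]:
    """Hash-check every stage output referenced by a manifest."""
    with open(manifest_path) as f:
        man = json.load(f)
    return {p: (Path(p).exists() and _sha256(Path(p)) == h)
            for p, h in man["outputs"].items()}
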