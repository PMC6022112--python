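"""End-to-end orchestration: simulate/load -> pretreat -> partition -> SiPLS ->
SPA -> calibrate -> evaluate.

The stage order mirrors the analytical workflow: spectra are pretreated
(MSC + SG first derivative), partitioned 2:1 by Kennard-Stone on the
pretreated spectra, reduced to informative intervals by SiPLS, thinned to the
characteristic wavelengths by SPA, and finally calibrated with PLSR and/or a
BPNN, reporting r_c, RMSEC, SECV, r_p, RMSEP and RPD.

Leak discipline: the prediction set's response values are read only by the
final evaluation.  The Kennard-Stone partition sees spectra only; the MSC
reference for modelling is the calibration-set mean; SPA is scored by
leave-one-out cross-validation on the calibration set, so the prediction set
is untouched until the final metrics.

One global seed fans out deterministically: ``SeedSequence(seed)`` generates
a state vector whose entries (mod 2^31) seed, in order, (0) the synthetic
generator and (1) the BPNN initialisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import (
    SpectraSet,
    read_response_csv,
    read_spectra_csv,
    write_response_csv,
    write_spectra_csv,
)
from .metrics import Metrics, evaluate, secv_loo
from .models import BPNNRegressor, PLS1Regression, pls1_loo_rmsecv
from .partition import KennardStoneSplitter, Partition, ks_partition, write_partition_csv
from .preprocessing import MSCCorrector, SavitzkyGolay, SGParams, _grid_spacing
from .selection import SiPLSResult, SPAResult, sipls_search, spa_select_cv
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["RunConfig", "RunReport", "run_pipeline", "model_to_dict", "model_from_dict"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    ``source`` is either ``{"synthetic": <SyntheticConfig dict or None>}`` or
    ``{"spectra_csv": path, "response_csv": path}``.  ``models`` lists model
    specs: ``{"type": "plsr", "max_components": int}`` or
    ``{"type": "bpnn", ...BPNNRegressor params}``.
    """

    source: dict = field(default_factory=lambda: {"synthetic": None})
    sg: SGParams = field(default_factory=SGParams)
    partition_ratio: float = 2.0
    sipls_n_values: tuple[int, ...] = tuple(range(5, 16))
    sipls_combo_sizes: tuple[int, ...] = (2, 3, 4)
    sipls_max_components: int = 10
    spa_n_max: int = 10
    models: tuple[dict, ...] = (
        {"type": "plsr", "max_components": 10},
        {"type": "bpnn"},
    )
    compute_secv: bool = True
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sg = d.get("pretreatment", {})
        missing = [
            k for k in ("spectra_csv", "response_csv")
            if "synthetic" not in d.get("input", {"synthetic": None}) and k not in d.get("input", {})
        ]
        if missing:
            raise ValueError(f"{path}: input section lacks {missing}")
        kwargs = dict(
            source=d.get("input", {"synthetic": None}),
            sg=SGParams(sg.get("window", 11), sg.get("polyorder", 3), sg.get("deriv", 1)),
            partition_ratio=d.get("partition_ratio", 2.0),
            seed=d.get("seed", 0),
            outdir=d.get("outdir"),
        )
        if "sipls" in d:
            s = d["sipls"]
            kwargs["sipls_n_values"] = tuple(s.get("n_values", range(5, 16)))
            kwargs["sipls_combo_sizes"] = tuple(s.get("combo_sizes", (2, 3, 4)))
            kwargs["sipls_max_components"] = s.get("max_components", 10)
        if "spa" in d:
            kwargs["spa_n_max"] = d["spa"].get("n_max", 10)
        if "models" in d:
            kwargs["models"] = tuple(d["models"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "input": self.source,
            "pretreatment": {"window": self.sg.window, "polyorder": self.sg.polyorder, "deriv": self.sg.deriv},
            "partition_ratio": self.partition_ratio,
            "sipls": {
                "n_values": list(self.sipls_n_values),
                "combo_sizes": list(self.sipls_combo_sizes),
                "max_components": self.sipls_max_components,
            },
            "spa": {"n_max": self.spa_n_max},
            "models": [dict(mm) for mm in self.models],
            "seed": self.seed,
            "outdir": self.outdir,
        }


@dataclass
class RunReport:
    """All artifacts of one pipeline run (in memory; files if outdir was set)."""

    config: RunConfig
    dataset: SpectraSet
    partition: Partition
    sipls: SiPLSResult
    spa: SPAResult
    selected_wavelengths: list[float]
    metrics: dict[str, Metrics]
    predictions: dict[str, dict[str, np.ndarray]]
    artifact_paths: dict[str, str] = field(default_factory=dict)


def _stage_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(2, dtype=np.uint64)
    return {"simulate": int(state[0] % 2**31), "bpnn": int(state[1] % 2**31)}


def _load_input(config: RunConfig, seeds: dict[str, int]) -> SpectraSet:
    src = config.source
    if "synthetic" in src:
        sc = src["synthetic"]
        syn = SyntheticConfig.from_dict(sc) if isinstance(sc, dict) else SyntheticConfig()
        syn.seed = seeds["simulate"]
        syn.__post_init__()  # revalidate
        return generate_dataset(syn)
    spectra = read_spectra_csv(src["spectra_csv"])
    responses = read_response_csv(src["response_csv"])
    missing = [sid for sid in spectra.sample_ids if sid not in responses]
    # samples with no response (e.g. a blinded prediction set) carry NaN until evaluation
    y = np.array([responses.get(sid, np.nan) for sid in spectra.sample_ids])
    if missing:
        logger.info("%d samples lack response values; usable only in the prediction set", len(missing))
    spectra.response = y
    return spectra


def _fit_model(spec: dict, X, y, seeds: dict[str, int]):
    kind = spec.get("type", "plsr").lower()
    if kind == "plsr":
        cap = min(spec.get("max_components", 10), X.shape[0] - 2, X.shape[1])
        curve = pls1_loo_rmsecv(X, y, cap)
        ncomp = int(np.argmin(curve)) + 1
        return "PLSR", PLS1Regression(n_components=ncomp).fit(X, y)
    if kind == "bpnn":
        params = {k: v for k, v in spec.items() if k != "type"}
        params.setdefault("random_state", seeds["bpnn"])
        return "BPNN", BPNNRegressor(**params).fit(X, y)
    raise ValueError(f"unknown model type {kind!r}")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``.

    Returns a :class:`RunReport`; if ``config.outdir`` is set, every stage
    artifact (partition CSV, SiPLS table, SPA curve, selected wavelengths,
    metrics at 2 d.p. plus a full-precision sidecar, config echo and summary)
    is also written there.
    """
    seeds = _stage_seeds(config.seed)
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _artifact(name: str) -> Path:
        paths[name] = str(outdir / name)
        return outdir / name

    # stage 1: input
    data = _load_input(config, seeds)
    if outdir and "synthetic" in config.source:
        write_spectra_csv(data, _artifact("spectra.csv"))
        write_response_csv(data, _artifact("response.csv"))

    # stage 2: partition on pretreated spectra (full-set MSC reference; spectra only)
    msc_all = MSCCorrector().fit(data.absorbance)
    delta = _grid_spacing(data)
    sg = SavitzkyGolay(config.sg.window, config.sg.polyorder, config.sg.deriv, delta=delta).fit(data.absorbance)
    pre_all = sg.transform(msc_all.transform(data.absorbance))
    part = ks_partition(data.with_absorbance(pre_all), ratio=config.partition_ratio)
    if outdir:
        write_partition_csv(part, _artifact("partition.csv"))

    id_to_row = {sid: i for i, sid in enumerate(data.sample_ids)}
    cal_idx = np.array([id_to_row[s] for s in part.calibration_ids])
    pred_idx = np.array([id_to_row[s] for s in part.prediction_ids])

    # stage 3: modelling pretreatment — MSC reference is the calibration mean
    msc_cal = MSCCorrector().fit(data.absorbance[cal_idx])
    X_cal = sg.transform(msc_cal.transform(data.absorbance[cal_idx]))
    X_pred = sg.transform(msc_cal.transform(data.absorbance[pred_idx]))
    y_cal = data.response[cal_idx]
    y_pred_true = data.response[pred_idx]
    if np.any(~np.isfinite(y_cal)):
        raise ValueError("calibration samples lack response values")

    # stage 4: SiPLS interval search on the calibration set
    sipls = sipls_search(
        X_cal,
        y_cal,
        N_values=config.sipls_n_values,
        combo_sizes=config.sipls_combo_sizes,
        max_components=config.sipls_max_components,
        wavelengths=data.grid,
    )
    if outdir:
        tbl = sipls.table.copy()
        tbl["intervals"] = tbl["intervals"].map(lambda t: "[" + " ".join(map(str, t)) + "]")
        tbl["rmsecv"] = tbl["rmsecv"].round(2)
        tbl.to_csv(_artifact("sipls_table.csv"), index=False)

    cols = sipls.selected_columns
    # stage 5: SPA on the retained columns, scored by calibration-set LOO
    # (keeps the prediction set untouched before final evaluation)
    spa = spa_select_cv(
        X_cal[:, cols],
        y_cal,
        n_max=min(config.spa_n_max, X_cal.shape[0] - 2, len(cols)),
        wavelengths=data.grid[cols],
    )
    sel_cols = cols[spa.selected_columns]  # absolute column indices, selection order
    sel_wl = [float(data.grid[j]) for j in sel_cols]
    if outdir:
        pd.DataFrame(
            {"n_variables": np.arange(1, spa.rmse_curve.size + 1), "rmse": spa.rmse_curve}
        ).to_csv(_artifact("spa_curve.csv"), index=False)
        pd.DataFrame({"wavelength_nm": sel_wl}).to_csv(_artifact("selected_wavelengths.csv"), index=False)

    # stage 6-7: calibrate and evaluate on the characteristic wavelengths
    Xc, Xp = X_cal[:, sel_cols], X_pred[:, sel_cols]
    metrics: dict[str, Metrics] = {}
    predictions: dict[str, dict[str, np.ndarray]] = {}
    for spec in config.models:
        name, model = _fit_model(spec, Xc, y_cal, seeds)
        yc_hat = model.predict(Xc)
        cal_m = evaluate(y_cal, yc_hat, "calibration")
        secv = secv_loo(model, Xc, y_cal) if config.compute_secv else None
        rec = Metrics(r_c=cal_m.r_c, rmsec=cal_m.rmsec, secv=secv)
        yp_hat = model.predict(Xp)
        if np.all(np.isfinite(y_pred_true)):
            pred_m = evaluate(y_pred_true, yp_hat, "prediction")
            rec.r_p, rec.rmsep, rec.sd, rec.rpd = pred_m.r_p, pred_m.rmsep, pred_m.sd, pred_m.rpd
        metrics[name] = rec
        predictions[name] = {"calibration": yc_hat, "prediction": yp_hat}

    if outdir:
        rows = [{"model": k, **v.as_dict()} for k, v in metrics.items()]
        full = pd.DataFrame(rows)
        full.to_csv(_artifact("metrics_full.csv"), index=False, float_format="%.17g")
        rounded = full.copy()
        for c in rounded.columns[1:]:
            rounded[c] = rounded[c].astype(float).round(2)
        rounded.to_csv(_artifact("metrics.csv"), index=False)
        with open(_artifact("config_echo.yaml"), "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
        _write_summary(_artifact("report.txt"), config, part, sipls, spa, sel_wl, metrics)

    return RunReport(
        config=config,
        dataset=data,
        partition=part,
        sipls=sipls,
        spa=spa,
        selected_wavelengths=sel_wl,
        metrics=metrics,
        predictions=predictions,
        artifact_paths=paths,
    )


def _write_summary(path, config, part, sipls, spa, sel_wl, metrics) -> None:
    lines = [
        "NIR wood-stiffness calibration run",
        f"seed: {config.seed}",
        f"partition: {len(part.calibration_ids)} calibration / {len(part.prediction_ids)} prediction "
        f"(ratio {config.partition_ratio}:1)",
        f"SiPLS best: N={sipls.best_n_intervals}, intervals "
        f"[{' '.join(map(str, sipls.best_intervals))}], {sipls.best_n_components} components, "
        f"RMSECV {sipls.best_rmsecv:.2f} GPa ({len(sipls.selected_columns)} columns retained)",
        f"SPA: {spa.n_selected} characteristic wavelengths: "
        + ", ".join(f"{w:.1f} nm" for w in sel_wl),
        "",
        "model   r_c    RMSEC  SECV   r_p    RMSEP  RPD",
    ]
    for name, m in metrics.items():
        def _f(v):
            return "  -  " if v is None else f"{v:5.2f}"
        lines.append(
            f"{name:<7} {_f(m.r_c)}  {_f(m.rmsec)}  {_f(m.secv)}  {_f(m.r_p)}  {_f(m.rmsep)}  {_f(m.rpd)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# model (de)serialisation for the CLI ----------------------------------------


def model_to_dict(name: str, model) -> dict:
    if isinstance(model, PLS1Regression):
        return {
            "type": "plsr",
            "n_components": model.n_components_,
            "coef": model.coef_.tolist(),
            "intercept": model.intercept_,
        }
    if isinstance(model, BPNNRegressor):
        return {
            "type": "bpnn",
            "x_min": model.x_min_.tolist(),
            "x_range": model.x_range_.tolist(),
            "y_min": model.y_min_,
            "y_range": model.y_range_,
            "W1": model.W1_.tolist(),
            "b1": model.b1_.tolist(),
            "w2": model.w2_.tolist(),
            "b2": float(model.b2_),
        }
    raise TypeError(f"cannot serialise model {name!r} of type {type(model).__name__}")


def model_from_dict(d: dict):
    if d["type"] == "plsr":
        m = PLS1Regression(n_components=d["n_components"])
        m.coef_ = np.array(d["coef"])
        m.intercept_ = float(d["intercept"])
        m.n_components_ = d["n_components"]
        return m
    if d["type"] == "bpnn":
        m = BPNNRegressor(random_state=0)
        m.x_min_ = np.array(d["x_min"])
        m.x_range_ = np.array(d["x_range"])
        m.y_min_ = float(d["y_min"])
        m.y_range_ = float(d["y_range"])
        m.W1_ = np.array(d["W1"])
        m.b1_ = np.array(d["b1"])
        m.w2_ = np.array(d["w2"])
        m.b2_ = float(d["b2"])
        return m
    raise ValueError(f"unknown serialised model type {d['type']!r}")
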