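"""Virtual cohort generation and virtual-population calibration.

Workflow: sample candidate patients log-uniformly within the published
parameter bounds -> relax each to its baseline steady state -> keep
the physiologically plausible ones (cell densities within literature
ranges, active disease DAS28-CRP > 3.2; mediator ranges are advisory
and only logged) -> simulate the therapy protocols -> select a virtual
population (Vpop) whose baseline score distribution and
placebo-corrected endpoint fractions match the clinical-trial targets
-> optionally enrich under-represented phenotypes by resampling near
them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import CompiledModel, N_CELLS
from .network import NetworkSpec
from .patient import VirtualPatient
from .pkpd import TherapyDriver, TrialProtocol
from .scoring import ScoreParameters, acr_category, classify_ir, das28_from_densities
from .tables import (
    CELL_RANGES,
    CELLS,
    MEDIATOR_RANGES,
    MIN_BASELINE_DAS,
    ODE_MEDIATORS,
    PARAMETER_BOUNDS,
    TRIAL_STATS,
)

log = logging.getLogger(__name__)

ENDPOINTS = ("ACR20", "ACR50", "ACR70", "das_lt_2_6", "das_lt_3_2")


@dataclass
class ParameterBounds:
    """Per-parameter sampling bounds (name -> (lower, upper))."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PARAMETER_BOUNDS)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if name not in PARAMETER_BOUNDS:
                raise KeyError(f"unknown varied parameter {name!r}")
            if not 0 < lo < hi:
                raise ValueError(f"bounds for {name} must satisfy 0 < lower < upper")

    def names(self) -> list[str]:
        return sorted(self.bounds)


@dataclass
class PlausibilityRanges:
    """Physiological screens applied to baseline steady states."""

    cell_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CELL_RANGES)
    )
    mediator_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(MEDIATOR_RANGES)
    )
    min_baseline_das: float = MIN_BASELINE_DAS

    def __post_init__(self) -> None:
        for name, (lo, hi) in {**self.cell_ranges, **self.mediator_ranges}.items():
            if not 0 < lo < hi:
                raise ValueError(f"range for {name} must be positive and ordered")


def placebo_correct(treatment_fraction: float, placebo_fraction: float) -> float:
    """Drug-attributable response fraction under independence.

    With independent drug and placebo response probabilities,
    P_obs = P_d + P_p - P_d*P_p, hence P_d = (P_obs - P_p)/(1 - P_p).
    """
    if placebo_fraction >= 1.0:
        raise ValueError("placebo fraction of 1 leaves the correction undefined")
    if not 0 <= placebo_fraction <= 1 or not 0 <= treatment_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if treatment_fraction < placebo_fraction:
        log.warning(
            "treatment fraction %.3f below placebo %.3f; corrected value clipped to 0",
            treatment_fraction, placebo_fraction,
        )
        return 0.0
    return (treatment_fraction - placebo_fraction) / (1.0 - placebo_fraction)


@dataclass
class CalibrationTargets:
    """Selection targets: baseline score statistics and
    placebo-corrected endpoint fractions per trial."""

    baseline_das: dict[str, tuple[float, float]] = field(default_factory=dict)
    endpoint_fractions: dict[tuple[str, str], float] = field(default_factory=dict)
    das_mean_tol: float = 0.3
    #: soft scale for the baseline-score spread; the sd enters the
    #: selection objective but not the convergence contract (no
    #: published tolerance accompanies it)
    das_sd_tol: float = 1.0
    endpoint_tol: float = 0.05

    def __post_init__(self) -> None:
        for key, v in self.endpoint_fractions.items():
            if not 0 <= v <= 1:
                raise ValueError(f"target fraction {key} outside [0, 1]")

    @classmethod
    def from_trial_stats(cls, stats: dict | None = None,
                         endpoints: tuple[str, ...] = ENDPOINTS) -> "CalibrationTargets":
        """Placebo-corrected targets from the published arm values."""
        stats = stats or TRIAL_STATS
        t = cls()
        for trial, d in stats.items():
            if d.get("baseline_das"):
                t.baseline_das[trial] = tuple(d["baseline_das"])
            for ep in endpoints:
                if ep in d["treatment"] and ep in d["placebo"]:
                    t.endpoint_fractions[(trial, ep)] = placebo_correct(
                        d["treatment"][ep] / 100.0, d["placebo"][ep] / 100.0
                    )
        return t


class PopulationTable:
    """Cohort/Vpop container: one row per patient.

    ``df`` holds baseline state, score, flags and therapy outcomes;
    ``params`` the sampled parameter values (one column per varied
    parameter); ``patients`` the in-memory parameter vectors.
    """

    def __init__(self, df: pd.DataFrame, params: pd.DataFrame | None = None,
                 patients: list[VirtualPatient] | None = None):
        self.df = df
        self.params = params if params is not None else pd.DataFrame(index=df.index)
        self.patients = patients or []

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "PopulationTable":
        idx = np.flatnonzero(np.asarray(mask))
        return PopulationTable(
            self.df.iloc[idx].reset_index(drop=True),
            self.params.iloc[idx].reset_index(drop=True),
            [self.patients[i] for i in idx] if self.patients else [],
        )

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat(
            [self.df.reset_index(drop=True),
             self.params.reset_index(drop=True).add_prefix("param__")],
            axis=1,
        )
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationTable":
        raw = pd.read_csv(path)
        pcols = [c for c in raw.columns if c.startswith("param__")]
        params = raw[pcols].rename(columns=lambda c: c.removeprefix("param__"))
        return cls(raw.drop(columns=pcols), params)


def sample_cohort(bounds: ParameterBounds, n: int, seed: int,
                  reference: VirtualPatient, prefix: str = "vp") -> tuple[list[VirtualPatient], pd.DataFrame]:
    """Draw ``n`` patients log-uniformly within the bounds.

    Each varied parameter is sampled independently; unvaried
    parameters stay at the reference patient's values.  Deterministic
    under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    names = bounds.names()
    lo = np.log(np.array([bounds.bounds[p][0] for p in names]))
    hi = np.log(np.array([bounds.bounds[p][1] for p in names]))
    draws = np.exp(rng.uniform(lo, hi, size=(n, len(names))))
    params = pd.DataFrame(draws, columns=names)
    patients = [
        reference.with_table_values(dict(zip(names, draws[i])), new_id=f"{prefix}{i:06d}")
        for i in range(n)
    ]
    return patients, params


def baseline_steady_states(spec: NetworkSpec, patients: list[VirtualPatient],
                           init_vector: np.ndarray, t_max: float = 500.0,
                           dt: float = 0.25, tol: float = 1e-5):
    """Batch-relax every patient to baseline steady state.

    Returns (Y, residuals, converged); Y rows are flat state vectors.
    """
    model = CompiledModel(spec, patients)
    Y0 = np.tile(np.asarray(init_vector, dtype=float), (len(patients), 1))
    return model.steady_state_batch(Y0, t_max=t_max, dt=dt, tol=tol)


def _state_frame(spec: NetworkSpec, patients: list[VirtualPatient], Y: np.ndarray) -> pd.DataFrame:
    model = CompiledModel(spec, patients)
    cols = {}
    for i, c in enumerate(CELLS):
        cols[f"{c}__cells_per_mL"] = Y[:, i]
    for j, m in enumerate(ODE_MEDIATORS):
        cols[f"{m}__ng_per_mL"] = Y[:, N_CELLS + j]
    cols["CAM__ng_per_mL"] = model.f_cam * spec.cam(Y[:, model.endo_idx]) if spec.cam else 0.0
    return pd.DataFrame(cols)


def filter_plausible(spec: NetworkSpec, patients: list[VirtualPatient],
                     params: pd.DataFrame, ranges: PlausibilityRanges,
                     init_vector: np.ndarray,
                     score_params: ScoreParameters | None = None,
                     t_max: float = 500.0, dt: float = 0.25) -> PopulationTable:
    """Relax to steady state and flag plausibility.

    A patient is plausible iff its steady state converged, every cell
    density lies within its literature range, and baseline DAS28-CRP
    exceeds the entry cutoff.  Mediator ranges are scored as a soft
    check (count recorded, never excluding), since cytokine
    measurements are less tissue-specific than cell counts.
    """
    Y, res, conv = baseline_steady_states(spec, patients, init_vector, t_max=t_max, dt=dt)
    df = _state_frame(spec, patients, Y)
    sp = score_params or ScoreParameters()
    density = {c: df[f"{c}__cells_per_mL"].to_numpy() for c in CELLS}
    das = das28_from_densities(density, sp)
    cells_ok = np.ones(len(patients), dtype=bool)
    for c, (lo, hi) in ranges.cell_ranges.items():
        cells_ok &= (density[c] >= lo) & (density[c] <= hi)
    med_ok = np.zeros(len(patients), dtype=int)
    for m, (lo, hi) in ranges.mediator_ranges.items():
        col = df[f"{m}__ng_per_mL"].to_numpy()
        med_ok += ((col >= lo) & (col <= hi)).astype(int)
    das_ok = das > ranges.min_baseline_das
    plausible = conv & cells_ok & das_ok
    n_exc = int(np.sum(~conv))
    if n_exc:
        log.info("excluded %d patients with non-converged steady states", n_exc)
    log.info(
        "plausibility: %d/%d plausible (cells in range: %d, DAS>%.1f: %d); "
        "median mediators-in-range %d/%d (advisory)",
        int(plausible.sum()), len(patients), int(cells_ok.sum()),
        ranges.min_baseline_das, int(das_ok.sum()),
        int(np.median(med_ok)), len(ranges.mediator_ranges),
    )
    df.insert(0, "id", [p.id for p in patients])
    df["das28_baseline"] = das
    df["steady_residual"] = res
    df["converged"] = conv
    df["cells_in_range"] = cells_ok
    df["mediators_in_range"] = med_ok
    df["plausible"] = plausible
    df["selected"] = False
    df["weight"] = 1.0
    return PopulationTable(df, params, patients)


def run_trial(population: PopulationTable, protocol: TrialProtocol,
              spec: NetworkSpec, score_params: ScoreParameters | None = None,
              driver: TherapyDriver | None = None, dt: float | None = None,
              label: str | None = None) -> PopulationTable:
    """Simulate one trial arm on the (entry-filtered) population.

    Adds outcome columns ``<label>_post_das``, ``<label>_pct``,
    ``<label>_ACR20/50/70``, ``<label>_das_lt_*`` and ``<label>_IR``
    in place and returns the population.  Entry criteria: minimum
    baseline DAS plus optional prior-therapy IR requirements, e.g.
    ``{"require_ir": ["MTX"]}``.
    """
    label = label or protocol.drug
    sp = score_params or ScoreParameters()
    entry = population.df["plausible"].to_numpy().copy()
    crit = protocol.entry_criteria
    min_das = crit.get("min_das", MIN_BASELINE_DAS)
    entry &= population.df["das28_baseline"].to_numpy() > min_das
    for prior in crit.get("require_ir", []):
        col = f"{prior}_IR"
        if col not in population.df:
            raise KeyError(f"entry criterion needs column {col}; run the {prior} trial first")
        entry &= population.df[col].fillna(False).to_numpy().astype(bool)
    idx = np.flatnonzero(entry)
    if len(idx) == 0:
        raise ValueError("entry criteria select zero patients")
    log.info("trial %s: %d patients enter", label, len(idx))

    patients = [population.patients[i] for i in idx]
    model = CompiledModel(spec, patients)
    Y0 = np.stack([_row_vector(population.df.iloc[i]) for i in idx])
    if driver is None:
        driver = TherapyDriver(protocol)
    if dt is None:
        dt = 0.05 if protocol.drug == "MTX" else 0.1
    Y = model.integrate(Y0, 0.0, protocol.readout_week * 7.0, dt,
                        driver if protocol.dose_mg > 0 else None)
    density = {c: Y[:, i] for i, c in enumerate(CELLS)}
    post = das28_from_densities(density, sp)

    n = len(population.df)
    cols = {f"{label}_post_das": np.full(n, np.nan), f"{label}_pct": np.full(n, np.nan)}
    flags = {k: np.zeros(n, dtype=bool) for k in
             (f"{label}_ACR20", f"{label}_ACR50", f"{label}_ACR70",
              f"{label}_das_lt_2_6", f"{label}_das_lt_3_2", f"{label}_delta_gt_1_2",
              f"{label}_IR")}
    base = population.df["das28_baseline"].to_numpy()
    for k, i in enumerate(idx):
        out = acr_category(base[i], post[k])
        cols[f"{label}_post_das"][i] = out.das28_post
        cols[f"{label}_pct"][i] = out.pct_reduction
        flags[f"{label}_ACR20"][i] = out.acr20
        flags[f"{label}_ACR50"][i] = out.acr50
        flags[f"{label}_ACR70"][i] = out.acr70
        flags[f"{label}_das_lt_2_6"][i] = out.das_lt_2_6
        flags[f"{label}_das_lt_3_2"][i] = out.das_lt_3_2
        flags[f"{label}_delta_gt_1_2"][i] = out.delta_gt_1_2
        flags[f"{label}_IR"][i] = classify_ir(out)
    entered = np.zeros(n, dtype=bool)
    entered[idx] = True
    population.df[f"{label}_entered"] = entered
    for k, v in {**cols, **flags}.items():
        population.df[k] = v
    return population


def _row_vector(row: pd.Series) -> np.ndarray:
    return np.array(
        [row[f"{c}__cells_per_mL"] for c in CELLS]
        + [row[f"{m}__ng_per_mL"] for m in ODE_MEDIATORS]
    )


# --- Vpop selection ------------------------------------------------------

@dataclass
class SelectionReport:
    converged: bool
    achieved: dict
    residuals: dict
    objective: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"converged": self.converged, "achieved": self.achieved,
             "residuals": self.residuals, "objective": self.objective}, indent=1))


def _endpoint_column(trial: str, ep: str) -> str:
    return f"{trial}_{ep}"


def select_vpop(population: PopulationTable, targets: CalibrationTargets,
                n_select: int = 300, seed: int = 0,
                n_iter: int = 40000, ir_das_trial: str | None = "TCZ",
                ir_subset_trials: tuple[str, ...] = ("TCZ",)) -> tuple[PopulationTable, SelectionReport]:
    """Select a Vpop matching baseline-score and endpoint targets.

    Histogram-matching importance weights on baseline DAS seed a
    subset which simulated annealing then refines against all targets
    (subset swap moves).  Endpoint fractions of trials listed in
    ``ir_subset_trials`` are evaluated over the MTX-IR members of the
    candidate subset, mirroring trials run on inadequate responders;
    ``ir_das_trial`` names the trial whose baseline-DAS target applies
    to that IR subset.  Returns the population with ``selected`` and
    ``weight`` columns set, plus a residual report.  If no subset
    meets every tolerance the best-effort subset is returned flagged
    not-converged.
    """
    rng = np.random.default_rng(seed)
    df = population.df
    pool = np.flatnonzero(df["plausible"].to_numpy())
    if len(pool) < n_select:
        raise ValueError(f"only {len(pool)} plausible patients for n_select={n_select}")
    das = df["das28_baseline"].to_numpy()

    # importance weights: target normal density over empirical density
    trial_das = targets.baseline_das.get("ADA") or next(iter(targets.baseline_das.values()), None)
    weights = np.ones(len(pool))
    if trial_das is not None:
        mu, sd = trial_das
        hist, edges = np.histogram(das[pool], bins=24)
        dens = hist[np.clip(np.searchsorted(edges, das[pool]) - 1, 0, len(hist) - 1)]
        dens = np.maximum(dens, 1) / len(pool)
        weights = np.exp(-0.5 * ((das[pool] - mu) / sd) ** 2) / dens
    weights /= weights.sum()

    endpoint_cols = {}
    for (trial, ep), tgt in targets.endpoint_fractions.items():
        col = _endpoint_column(trial, ep)
        if col in df.columns:
            vals = df[col].to_numpy().astype(float)
            ent = f"{trial}_entered"
            if ent in df.columns:
                vals = np.where(df[ent].fillna(False).to_numpy().astype(bool), vals, np.nan)
            endpoint_cols[(trial, ep)] = (vals, tgt, trial in ir_subset_trials)
    mtx_ir = df["MTX_IR"].to_numpy().astype(bool) if "MTX_IR" in df else np.zeros(len(df), bool)

    # per-patient feature columns so swap moves update sums in O(1):
    # das moments (overall and over the MTX-IR subset) and, per
    # endpoint, a numerator (responder) and denominator (entered) count
    feat_cols = [das, das**2, mtx_ir.astype(float), das * mtx_ir, das**2 * mtx_ir]
    ep_keys = list(endpoint_cols)
    for trial, ep in ep_keys:
        col, _, on_ir = endpoint_cols[(trial, ep)]
        valid = ~np.isnan(col)
        if on_ir:
            valid &= mtx_ir
        feat_cols.append(np.where(valid, np.nan_to_num(col), 0.0))
        feat_cols.append(valid.astype(float))
    feat = np.column_stack(feat_cols)

    def stats_from_sums(S: np.ndarray) -> tuple[float, dict, dict]:
        ach, res = {}, {}
        obj = 0.0
        for trial, (mu, sd) in targets.baseline_das.items():
            if trial == ir_das_trial:
                cnt, s1, s2 = S[2], S[3], S[4]
                if cnt < 5:
                    continue
            else:
                cnt, s1, s2 = float(n_select), S[0], S[1]
            m = s1 / cnt
            s = float(np.sqrt(max(s2 / cnt - m * m, 0.0)))
            ach[f"{trial}_das_mean"], ach[f"{trial}_das_sd"] = m, s
            res[f"{trial}_das_mean"], res[f"{trial}_das_sd"] = m - mu, s - sd
            obj += ((m - mu) / targets.das_mean_tol) ** 2
            obj += ((s - sd) / targets.das_sd_tol) ** 2
        for k, (trial, ep) in enumerate(ep_keys):
            _, tgt, _ = endpoint_cols[(trial, ep)]
            num, den = S[5 + 2 * k], S[6 + 2 * k]
            frac = num / den if den > 0 else 0.0
            ach[f"{trial}_{ep}"] = frac
            res[f"{trial}_{ep}"] = frac - tgt
            obj += ((frac - tgt) / targets.endpoint_tol) ** 2
        return obj, ach, res

    sel = rng.choice(pool, size=n_select, replace=False, p=weights)
    in_sel = np.zeros(len(df), dtype=bool)
    in_sel[sel] = True
    S = feat[sel].sum(axis=0)
    obj, _, _ = stats_from_sums(S)
    best_obj, best_sel = obj, sel.copy()
    sel_list = sel.copy()
    unsel_list = np.setdiff1d(pool, sel)
    temp0 = max(obj / 20.0, 0.5)
    n_polish = n_iter // 2
    for it in range(n_iter):
        i = int(rng.integers(len(sel_list)))
        j = int(rng.integers(len(unsel_list)))
        a, b = sel_list[i], unsel_list[j]
        S_new = S + feat[b] - feat[a]
        new_obj, _, _ = stats_from_sums(S_new)
        temp = temp0 * np.exp(-8.0 * it / n_iter)
        if new_obj <= obj or rng.random() < np.exp(-(new_obj - obj) / max(temp, 1e-9)):
            obj, S = new_obj, S_new
            sel_list[i], unsel_list[j] = b, a
            if obj < best_obj:
                best_obj, best_sel = obj, sel_list.copy()
        if best_obj < 1e-6:
            break
    # greedy polish from the best subset found
    sel_list = best_sel.copy()
    unsel_list = np.setdiff1d(pool, sel_list)
    S = feat[sel_list].sum(axis=0)
    obj = best_obj
    for _ in range(n_polish):
        i = int(rng.integers(len(sel_list)))
        j = int(rng.integers(len(unsel_list)))
        a, b = sel_list[i], unsel_list[j]
        S_new = S + feat[b] - feat[a]
        new_obj, _, _ = stats_from_sums(S_new)
        if new_obj < obj:
            obj, S = new_obj, S_new
            sel_list[i], unsel_list[j] = b, a
    best_sel = sel_list

    best_mask = np.zeros(len(df), dtype=bool)
    best_mask[best_sel] = True
    obj, ach, res = stats_from_sums(feat[best_sel].sum(axis=0))
    converged = all(
        abs(res[f"{t}_das_mean"]) <= targets.das_mean_tol
        for t in targets.baseline_das if f"{t}_das_mean" in res
    ) and all(
        abs(res[f"{t}_{e}"]) <= targets.endpoint_tol
        for (t, e) in endpoint_cols if f"{t}_{e}" in res
    )
    df["selected"] = best_mask
    w = np.zeros(len(df))
    w[pool] = weights * len(pool)
    df["weight"] = w
    report = SelectionReport(converged=converged, achieved=ach, residuals=res,
                             objective=float(obj))
    if not converged:
        log.warning("Vpop selection did not meet all tolerances: %s", res)
    return population, report


def enrich_cohort(population: PopulationTable, underrepresented_ids: list[str],
                  shrink_factor: float, n_new: int, seed: int,
                  bounds: ParameterBounds | None = None,
                  reference: VirtualPatient | None = None) -> tuple[list[VirtualPatient], pd.DataFrame]:
    """Resample near under-represented plausible patients.

    New candidates are drawn log-uniformly in a box of width
    ``shrink_factor`` times the global log-range, centered on each
    seed patient and clipped to the global bounds; they must then pass
    ``filter_plausible`` like any candidate.
    """
    if not 0 < shrink_factor < 1:
        raise ValueError("shrink_factor must lie in (0, 1)")
    bounds = bounds or ParameterBounds()
    rng = np.random.default_rng(seed)
    names = bounds.names()
    lo = np.log(np.array([bounds.bounds[p][0] for p in names]))
    hi = np.log(np.array([bounds.bounds[p][1] for p in names]))
    half = 0.5 * shrink_factor * (hi - lo)
    ids = list(population.df["id"])
    out_patients: list[VirtualPatient] = []
    rows = []
    per_seed = [n_new // len(underrepresented_ids)] * len(underrepresented_ids)
    for k in range(n_new - sum(per_seed)):
        per_seed[k] += 1
    for sid, m in zip(underrepresented_ids, per_seed):
        if sid not in ids:
            raise KeyError(f"unknown patient id {sid!r}")
        row = population.params.iloc[ids.index(sid)]
        center = np.log(row[names].to_numpy(dtype=float))
        ref = reference or population.patients[ids.index(sid)]
        for k in range(m):
            draw = rng.uniform(np.clip(center - half, lo, hi), np.clip(center + half, lo, hi))
            vals = dict(zip(names, np.exp(draw)))
            out_patients.append(ref.with_table_values(vals, new_id=f"{sid}_enr{k:04d}"))
            rows.append(vals)
    return out_patients, pd.DataFrame(rows)
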