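"""Monte Carlo variable screening over a predictor collection.

Many independent small model fits — each on a random subset of V variables
(default: random pairs) — are spread across C logical workers.  Each worker
runs a "sprint" of R sequential fits and maintains a tally table recording,
per variable, how many times it was used and its accumulated permutation
importance; tally tables are written to a shared directory as ``<id>.tt``
files.  Aggregation concatenates the tallies, computes each variable's
average permutation importance, and ranks the collection to reveal the top
contributors.  Three such ensembles are averaged by default before settling
on the top-k set.

Scheduling: to give every variable an expected S samples with V variables
per run, C_max = ceil(N·S / V) runs are needed; on C cores each worker
repeats R = ceil(C_max / C) runs, so the ensemble totals R·C runs and the
achieved sampling rate R·C·V/N is at least S.  The estimated fully-parallel
wall time for an observed ensemble time T is T/R.
"""

from __future__ import annotations

import logging
import math
import tempfile
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import maxent
from .rasters_io import OccurrenceSet, PredictorCollection, extract

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration and scheduling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenConfig:
    """Ensemble screening settings.

    ``C`` is the *logical* worker count: it fixes the schedule (R, total
    runs) and the per-worker random streams.  How many OS processes
    actually execute the workers is an execution detail (see ``screen``'s
    ``n_jobs``) and never changes the result.
    """

    S: int = 50
    V: int = 2
    C: int = 10
    top_k: int = 6
    n_ensembles: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.V < 2:
            raise ValueError("V must be at least 2")
        if self.S < 1 or self.C < 1:
            raise ValueError("S and C must be at least 1")


@dataclass(frozen=True)
class SchedulePlan:
    """Derived ensemble schedule: C_max, per-worker repeats, totals."""

    n_variables: int
    s_target: int
    v_per_run: int
    n_workers: int
    c_max: int
    repeat_factor_r: int
    runs_total: int
    achieved_s: float

    @property
    def runs_per_worker(self) -> int:
        return self.repeat_factor_r


def plan_ensemble(n_variables: int, s_target: int, v_per_run: int, n_workers: int) -> SchedulePlan:
    """Compute the ensemble schedule (C_max, R, total runs, achieved S)."""
    if v_per_run > n_variables:
        raise ValueError(
            f"V={v_per_run} exceeds collection size N={n_variables}"
        )
    c_max = math.ceil(n_variables * s_target / v_per_run)
    repeat = math.ceil(c_max / n_workers)
    runs_total = repeat * n_workers
    return SchedulePlan(
        n_variables=n_variables,
        s_target=s_target,
        v_per_run=v_per_run,
        n_workers=n_workers,
        c_max=c_max,
        repeat_factor_r=repeat,
        runs_total=runs_total,
        achieved_s=runs_total * v_per_run / n_variables,
    )


def estimate_tmin(t_observed: float, repeat_factor: int) -> float:
    """Fully-parallel time estimate T/R, reported to one decimal (minutes)."""
    if repeat_factor < 1:
        raise ValueError("repeat factor must be at least 1")
    if t_observed < 0:
        raise ValueError("observed time must be nonnegative")
    return round(t_observed / repeat_factor, 1)


def draw_variable_subset(
    names: Sequence[str], v: int, rng: np.random.Generator
) -> list[str]:
    """Uniform draw of v distinct variable names (subset-level replacement)."""
    names = list(names)
    if v > len(names):
        raise ValueError("subset size exceeds collection size")
    idx = rng.choice(len(names), size=v, replace=False)
    return [names[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# Tally tables
# ---------------------------------------------------------------------------

TALLY_HEADER = "variable\tuse_count\tcum_importance"


@dataclass
class TallyTable:
    """Per-variable (use count, accumulated permutation importance)."""

    counts: dict[str, int] = field(default_factory=dict)
    cum_importance: dict[str, float] = field(default_factory=dict)
    runs_completed: int = 0
    runs_attempted: int = 0

    def add_run(self, importance: dict[str, float]) -> None:
        for var, imp in importance.items():
            self.counts[var] = self.counts.get(var, 0) + 1
            self.cum_importance[var] = self.cum_importance.get(var, 0.0) + imp
        self.runs_completed += 1

    def merge(self, other: "TallyTable") -> None:
        for var, c in other.counts.items():
            self.counts[var] = self.counts.get(var, 0) + c
            self.cum_importance[var] = (
                self.cum_importance.get(var, 0.0) + other.cum_importance.get(var, 0.0)
            )
        self.runs_completed += other.runs_completed
        self.runs_attempted += other.runs_attempted

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(TALLY_HEADER + "\n")
            for var in sorted(self.counts):
                fh.write(f"{var}\t{self.counts[var]}\t{self.cum_importance[var]!r}\n")

    @classmethod
    def read(cls, path: str | Path) -> "TallyTable":
        tt = cls()
        with open(path) as fh:
            header = fh.readline().strip()
            if header != TALLY_HEADER:
                raise ValueError(f"{path}: bad tally header {header!r}")
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}: malformed tally row {line!r}")
                var, count, cum = parts
                tt.counts[var] = int(count)
                tt.cum_importance[var] = float(cum)
        # run counts are not serialized; file-based aggregation reports 0
        return tt


# ---------------------------------------------------------------------------
# Sprints
# ---------------------------------------------------------------------------

def run_sprint(
    collection: PredictorCollection,
    occurrences: OccurrenceSet,
    background: np.ndarray,
    plan: SchedulePlan,
    worker_id: int,
    seed: int,
    engine_config: maxent.EngineConfig | None = None,
    tally_dir: str | Path | None = None,
) -> TallyTable:
    """Execute one worker's sprint of R sequential random-subset fits.

    For each run: draw a variable subset, extract covariates at presences
    and background, drop rows that hit nodata *in the active subset only*,
    fit with the engine defaults, and add the replicate-averaged permutation
    importance to the tally.  A failed fit (non-convergence or degenerate
    subset) is logged and skipped without retry; its variables' counts are
    not incremented.  The tally is written to ``<tally_dir>/<worker_id>.tt``.
    """
    engine_config = engine_config or maxent.EngineConfig()
    names = collection.names
    pres_all, _ = extract(collection, names, occurrences.points)
    bg_all, _ = extract(collection, names, background)
    col_of = {v: j for j, v in enumerate(names)}

    tally = TallyTable()
    for run_idx in range(plan.runs_per_worker):
        rng = np.random.default_rng(np.random.SeedSequence((seed, run_idx)))
        subset = draw_variable_subset(names, plan.v_per_run, rng)
        tally.runs_attempted += 1
        cols = [col_of[v] for v in subset]
        pres = pres_all[:, cols]
        bg = bg_all[:, cols]
        pres = pres[~np.isnan(pres).any(axis=1)]
        bg = bg[~np.isnan(bg).any(axis=1)]
        run_seed = int(rng.integers(0, 2**31 - 1))
        cfg = replace(engine_config, seed=run_seed)
        try:
            cv = maxent.cross_validate(pres, bg, cfg, variables=subset, fit_full=False)
        except (maxent.ConvergenceError, maxent.DegenerateDataError, ValueError) as exc:
            logger.warning(
                "worker %d run %d on %s failed (%s); skipped without retry",
                worker_id, run_idx, subset, exc,
            )
            continue
        tally.add_run(cv.mean_importance)
    if tally_dir is not None:
        tally.write(Path(tally_dir) / f"{worker_id}.tt")
    return tally


# ---------------------------------------------------------------------------
# Aggregation and ranking
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Ranked screening outcome: per-variable tallies and the top-k set."""

    use_count: dict[str, int]
    cum_importance: dict[str, float]
    avg_importance: dict[str, float]
    ranking: list[str]
    top_k: list[str]
    runs_completed: int = 0
    runs_attempted: int = 0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("variable\tuse_count\tcum_importance\tavg_importance\trank\n")
            rank_of = {v: r + 1 for r, v in enumerate(self.ranking)}
            for var in self.ranking:
                fh.write(
                    f"{var}\t{self.use_count.get(var, 0)}\t"
                    f"{self.cum_importance.get(var, 0.0):.6f}\t"
                    f"{self.avg_importance[var]:.6f}\t{rank_of[var]}\n"
                )


def _rank(avg: dict[str, float], counts: dict[str, int]) -> list[str]:
    # descending importance; ties broken by higher use count, then name
    return sorted(avg, key=lambda v: (-avg[v], -counts.get(v, 0), v))


def aggregate(
    tally_files: Iterable[str | Path] | str | Path, top_k: int = 6
) -> ScreenResult:
    """Concatenate worker tally files into a global ranked result.

    Accepts a directory (every ``*.tt`` file inside) or an iterable of
    paths.  Element-wise sums are order-independent; a malformed file is
    rejected with a log message and aggregation continues.  Unused
    variables are excluded from the ranking.
    """
    if isinstance(tally_files, (str, Path)) and Path(tally_files).is_dir():
        files = sorted(Path(tally_files).glob("*.tt"))
    else:
        files = [Path(p) for p in tally_files]  # type: ignore[union-attr]
    total = TallyTable()
    n_ok = 0
    for path in sorted(files):
        try:
            tt = TallyTable.read(path)
        except (ValueError, OSError) as exc:
            logger.error("rejecting tally file %s: %s", path, exc)
            continue
        total.merge(tt)
        n_ok += 1
    if n_ok == 0:
        raise RuntimeError("no usable tally files to aggregate")
    return _tally_to_result(total, top_k)


def _tally_to_result(total: TallyTable, top_k: int) -> ScreenResult:
    avg = {
        v: total.cum_importance.get(v, 0.0) / c
        for v, c in total.counts.items()
        if c > 0
    }
    ranking = _rank(avg, total.counts)
    return ScreenResult(
        use_count=dict(total.counts),
        cum_importance=dict(total.cum_importance),
        avg_importance=avg,
        ranking=ranking,
        top_k=ranking[:top_k],
        runs_completed=total.runs_completed,
        runs_attempted=total.runs_attempted,
    )


# ---------------------------------------------------------------------------
# Full ensemble screening
# ---------------------------------------------------------------------------

def _sprint_job(args) -> TallyTable:
    (collection, occurrences, background, plan, worker_id, seed, engine_config, tally_dir) = args
    return run_sprint(
        collection, occurrences, background, plan, worker_id, seed,
        engine_config=engine_config, tally_dir=tally_dir,
    )


def _worker_seed(master_seed: int, ensemble: int, worker: int) -> int:
    ss = np.random.SeedSequence((master_seed, 1000 + ensemble, worker))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_ensemble(
    collection: PredictorCollection,
    occurrences: OccurrenceSet,
    background: np.ndarray,
    plan: SchedulePlan,
    master_seed: int,
    ensemble_idx: int = 0,
    engine_config: maxent.EngineConfig | None = None,
    tally_dir: str | Path | None = None,
    n_jobs: int = 1,
    top_k: int = 6,
) -> ScreenResult:
    """Run one full ensemble (C sprints) and aggregate its tallies."""
    own_tmp = None
    if tally_dir is None:
        own_tmp = tempfile.TemporaryDirectory(prefix="nichescreen-tt-")
        tally_dir = own_tmp.name
    tally_dir = Path(tally_dir)
    tally_dir.mkdir(parents=True, exist_ok=True)
    jobs = [
        (
            collection, occurrences, background, plan, w,
            _worker_seed(master_seed, ensemble_idx, w), engine_config, str(tally_dir),
        )
        for w in range(plan.n_workers)
    ]
    tallies: list[TallyTable]
    if n_jobs <= 1:
        tallies = [_sprint_job(j) for j in jobs]
    else:
        with ProcessPoolExecutor(max_workers=n_jobs) as pool:
            tallies = list(pool.map(_sprint_job, jobs))
    total = TallyTable()
    for tt in tallies:
        total.merge(tt)
    result = _tally_to_result(total, top_k)
    shortfall = plan.runs_total - total.runs_completed
    if shortfall:
        logger.warning(
            "ensemble %d: %d/%d runs failed; achieved S = %.2f (target %d)",
            ensemble_idx, shortfall, plan.runs_total,
            total.runs_completed * plan.v_per_run / plan.n_variables, plan.s_target,
        )
    if own_tmp is not None:
        own_tmp.cleanup()
    return result


def screen(
    collection: PredictorCollection,
    occurrences: OccurrenceSet,
    config: ScreenConfig | None = None,
    engine_config: maxent.EngineConfig | None = None,
    n_jobs: int = 1,
    workdir: str | Path | None = None,
) -> ScreenResult:
    """Full screening: n_ensembles independent ensembles, averaged.

    Each ensemble draws its own background sample and worker seed streams
    (all derived from ``config.seed``); per-variable average importances
    are averaged across the ensembles in which the variable was used, then
    re-ranked to produce the final top-k.
    """
    from .rasters_io import sample_background

    config = config or ScreenConfig()
    engine_config = engine_config or maxent.EngineConfig()
    plan = plan_ensemble(len(collection), config.S, config.V, config.C)
    logger.info(
        "screening %d variables: C_max=%d, R=%d, %d runs/ensemble × %d ensembles",
        plan.n_variables, plan.c_max, plan.repeat_factor_r, plan.runs_total,
        config.n_ensembles,
    )
    per_ensemble: list[ScreenResult] = []
    for e in range(config.n_ensembles):
        bg_seed = int(
            np.random.SeedSequence((config.seed, 2000 + e)).generate_state(1)[0]
            % (2**31 - 1)
        )
        background = sample_background(collection, engine_config.n_background, bg_seed)
        tdir = None if workdir is None else Path(workdir) / f"ensemble_{e}"
        per_ensemble.append(
            run_ensemble(
                collection, occurrences, background, plan,
                master_seed=config.seed, ensemble_idx=e,
                engine_config=engine_config, tally_dir=tdir, n_jobs=n_jobs,
                top_k=config.top_k,
            )
        )
    if config.n_ensembles == 1:
        return per_ensemble[0]
    # average per-variable avg_importance over ensembles where the variable
    # was used; combined counts are summed for reporting
    avg: dict[str, float] = {}
    counts: dict[str, int] = {}
    cum: dict[str, float] = {}
    for res in per_ensemble:
        for v, a in res.avg_importance.items():
            avg[v] = avg.get(v, 0.0) + a
            counts[v] = counts.get(v, 0) + res.use_count[v]
            cum[v] = cum.get(v, 0.0) + res.cum_importance[v]
    n_seen = {
        v: sum(1 for res in per_ensemble if v in res.avg_importance) for v in avg
    }
    avg = {v: a / n_seen[v] for v, a in avg.items()}
    ranking = _rank(avg, counts)
    return ScreenResult(
        use_count=counts,
        cum_importance=cum,
        avg_importance=avg,
        ranking=ranking,
        top_k=ranking[: config.top_k],
        runs_completed=sum(r.runs_completed for r in per_ensemble),
        runs_attempted=sum(r.runs_attempted for r in per_ensemble),
    )
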