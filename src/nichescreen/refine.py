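"""Predictor refinement: pairwise collinearity analysis and elimination.

For the variables that survive screening, Pearson r, r² and the pairwise
variance inflation factor VIF = 1/(1−r²) are computed over the same
presence+background covariate rows used for model fitting.  Any pair whose
statistics exceed the thresholds (defaults r > 0.8, r² > 0.8, VIF > 10,
each applied to |r|) is flagged, and the pair member with the lower
screening importance is dropped; flags are recomputed among survivors until
no pair is flagged.

By default a pair is flagged when *any* threshold is exceeded; note
r > 0.8 alone already implies flagging under the defaults, so the default
rule is binding at |r| > 0.8.  A conjunctive reading (all three thresholds
simultaneously, binding at |r| > 0.949) is available via ``rule="all"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CollinearityThresholds:
    r: float = 0.8
    r2: float = 0.8
    vif: float = 10.0
    rule: str = "any"  # "any" | "all"

    def flags(self, r_abs: float) -> bool:
        r2 = r_abs * r_abs
        vif = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
        checks = (r_abs > self.r, r2 > self.r2, vif > self.vif)
        return any(checks) if self.rule == "any" else all(checks)


@dataclass
class CollinearityReport:
    """Pairwise r/r²/VIF matrices plus the elimination record."""

    variables: list[str]
    r: np.ndarray
    r2: np.ndarray
    vif: np.ndarray
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (variable, reason)
    retained: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for label, mat in (("r", self.r), ("r2", self.r2), ("vif", self.vif)):
                fh.write(f"# {label}\nvariable\t" + "\t".join(self.variables) + "\n")
                for i, v in enumerate(self.variables):
                    fh.write(v + "\t" + "\t".join(f"{x:.6g}" for x in mat[i]) + "\n")
            fh.write("# flagged pairs\n")
            for a, b in self.flagged_pairs:
                fh.write(f"{a}\t{b}\n")
            fh.write("# dropped\n")
            for v, reason in self.dropped:
                fh.write(f"{v}\t{reason}\n")
            fh.write("# retained\n")
            for v in self.retained:
                fh.write(v + "\n")


def collinearity(covariate_rows: np.ndarray, variables: list[str]) -> CollinearityReport:
    """Pairwise Pearson r, r² and VIF = 1/(1−r²) over covariate rows.

    VIF is +inf where r² = 1.  Constant columns are an error: correlation
    is undefined for them and they should have been dropped upstream.
    """
    x = np.atleast_2d(np.asarray(covariate_rows, dtype=float))
    x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] < 3:
        raise ValueError("need at least 3 complete rows for correlation")
    if x.shape[1] != len(variables):
        raise ValueError("column count does not match variable list")
    sd = x.std(axis=0)
    for v, s in zip(variables, sd):
        if s == 0:
            raise ValueError(f"variable {v!r} is constant over the supplied rows")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    r2 = r * r
    with np.errstate(divide="ignore"):
        # r² within one ulp of 1 is numerically perfect collinearity
        vif = np.where(r2 >= 1.0 - 1e-12, np.inf, 1.0 / (1.0 - np.minimum(r2, 1.0 - 1e-300)))
    np.fill_diagonal(vif, np.inf)
    return CollinearityReport(variables=list(variables), r=r, r2=r2, vif=vif)


def _flagged_pairs(
    report: CollinearityReport,
    active: list[str],
    thresholds: CollinearityThresholds,
) -> list[tuple[str, str]]:
    idx = {v: i for i, v in enumerate(report.variables)}
    pairs = []
    for a in range(len(active)):
        for b in range(a + 1, len(active)):
            va, vb = active[a], active[b]
            if thresholds.flags(abs(float(report.r[idx[va], idx[vb]]))):
                pairs.append((va, vb))
    return pairs


def eliminate(
    report: CollinearityReport,
    importance_ranking: dict[str, float],
    thresholds: CollinearityThresholds | None = None,
) -> CollinearityReport:
    """Iteratively drop the least-contributing member of flagged pairs.

    While any surviving pair is flagged, the variable with the lowest
    importance among all flagged-pair members is dropped (one drop per
    iteration, so a variable collinear with several others is dropped at
    most once), and flags are recomputed among survivors.  Deterministic
    given the importance ranking; importance ties break toward dropping the
    lexicographically later name.
    """
    thresholds = thresholds or CollinearityThresholds()
    missing = set(report.variables) - set(importance_ranking)
    if missing:
        raise ValueError(f"importance ranking missing variables {sorted(missing)}")
    active = list(report.variables)
    dropped: list[tuple[str, str]] = []
    report.flagged_pairs = _flagged_pairs(report, active, thresholds)
    flagged = list(report.flagged_pairs)
    while flagged:
        members = sorted({v for pair in flagged for v in pair})
        victim = min(members, key=lambda v: (importance_ranking[v], [-ord(c) for c in v]))
        partners = sorted({a if b == victim else b for a, b in flagged if victim in (a, b)})
        dropped.append((victim, f"collinear with {','.join(partners)}"))
        logger.info("refine: dropping %r (collinear with %s)", victim, partners)
        active = [v for v in active if v != victim]
        flagged = _flagged_pairs(report, active, thresholds)
    report.dropped = dropped
    report.retained = active
    return report
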