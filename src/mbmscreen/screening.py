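"""Motif matching and the binding-potential / fit-value scoring model.

A candidate pharmacophore is aligned into the MBM reference frame via its
ligand pose and matched feature-to-feature (same kind, within a pair cutoff)
by an assignment that maximises the number of matched features ``n`` and,
among maximum matchings, minimises the total pair distance.  The match is
scored by the binding potential

    BP = n**alpha * RMSD**beta        (alpha > 0, beta < 0)

and mapped to a fit value in [0, 1) by a sigmoid of log(BP/BP0), where BP0
is the reference binding potential (the weakest proven target).  Under the
natural-log convention the sigmoid simplifies exactly to BP/(BP + BP0); the
base-10 convention is kept as an option.  A candidate is flagged a highly
potential target (HPT) when fit value >= threshold (default 0.5, the
fit of the reference target itself).

``calibrate`` recovers (alpha, beta, kappa) from dissociation-constant
observations under a pluggable BP–K_D link; the default link reads
log10(BP) = 1/K_D - kappa, so 1/K_D is linear in (log10 n, log10 RMSD, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .mbm import MBM, align_to_reference
from .pharmacophore import Pharmacophore

__all__ = [
    "MatchResult",
    "ScoringParams",
    "ScreeningRecord",
    "KdObservation",
    "ReciprocalKdLink",
    "CalibrationResult",
    "UnidentifiableError",
    "match",
    "binding_potential",
    "fit_value",
    "screen",
    "screen_fit_values",
    "calibrate",
    "report_to_dataframe",
]

DEFAULT_PAIR_CUTOFF = 2.0  # Å


class UnidentifiableError(ValueError):
    """Calibration design matrix is rank-deficient."""


@dataclass(frozen=True)
class ScoringParams:
    """Constants of the BP / fit-value model.

    alpha, beta are the exponents on n and RMSD; kappa the K_D-link constant;
    bp0 the reference binding potential anchoring fit = 0.5.  ``rmsd_floor``
    clamps RMSD before exponentiation (beta < 0 is singular at 0), and
    ``rmsd_mode`` selects root-mean-square ("rms") or arithmetic-mean
    ("mean") pair distance.
    """

    alpha: float = 2.599
    beta: float = -5.234
    kappa: float = -5.905
    bp0: float = 49.243
    threshold: float = 0.5
    log_convention: str = "natural"  # "natural" | "base10"
    rmsd_floor: float = 0.1  # Å
    rmsd_mode: str = "rms"  # "rms" | "mean"

    def __post_init__(self):
        if self.bp0 <= 0:
            raise ValueError("bp0 must be > 0")
        if self.rmsd_floor <= 0:
            raise ValueError("rmsd_floor must be > 0")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")
        if self.log_convention not in ("natural", "base10"):
            raise ValueError("log_convention must be 'natural' or 'base10'")
        if self.rmsd_mode not in ("rms", "mean"):
            raise ValueError("rmsd_mode must be 'rms' or 'mean'")


@dataclass(frozen=True)
class MatchResult:
    n: int
    rmsd: float
    pairs: tuple[tuple[int, int], ...]  # (candidate index, mbm index)
    unmatched_candidate: tuple[int, ...]
    unmatched_mbm: tuple[int, ...]
    total_distance: float = 0.0

    def __post_init__(self):
        if self.n != len(self.pairs):
            raise ValueError("n must equal number of pairs")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")


@dataclass(frozen=True)
class ScreeningRecord:
    target_id: str
    source_structure: str
    n: int
    rmsd: float
    bp: float
    fit_value: float
    is_hpt: bool


@dataclass(frozen=True)
class KdObservation:
    target_id: str
    n: int
    rmsd: float
    kd: float  # dissociation constant; unit carried in `kd_unit`
    kd_unit: str = "uM"

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


# ---------------------------------------------------------------------------
# matching

def _assign_one_kind(cand: np.ndarray, ref: np.ndarray, cutoff: float):
    """Max-cardinality, then min-total-distance assignment within one kind."""
    d = np.linalg.norm(cand[:, None, :] - ref[None, :, :], axis=-1)
    big = 1.0e6 * (1.0 + cutoff) * (d.size + 1)
    cost = np.where(d <= cutoff, d, big)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if d[i, j] <= cutoff]
    return pairs, d


def match(
    candidate: Pharmacophore,
    mbm: MBM,
    pair_cutoff: float = DEFAULT_PAIR_CUTOFF,
    *,
    rmsd_mode: str = "rms",
    align: bool = True,
) -> MatchResult:
    """Assign candidate features to MBM features and measure (n, RMSD).

    Pairs are restricted to same-kind features within ``pair_cutoff`` after
    aligning the candidate into the MBM frame through its ligand pose
    (``align=False`` if the candidate is already in that frame).  The
    assignment maximises n, breaking ties by minimum total distance, then by
    lexicographic pair order.  n = 0 is a valid result, not an error.
    """
    if pair_cutoff <= 0:
        raise ValueError("pair_cutoff must be > 0")
    feats = candidate.features
    if align:
        tf = align_to_reference(candidate.ligand_pose, mbm.reference_ligand)
        feats = [f.moved(tf.rotation, tf.translation) for f in feats]

    pairs: list[tuple[int, int]] = []
    dists: list[float] = []
    kinds = sorted({f.kind for f in feats} & {f.kind for f in mbm.features})
    for kind in kinds:
        ci = [i for i, f in enumerate(feats) if f.kind == kind]
        mi = [j for j, f in enumerate(mbm.features) if f.kind == kind]
        cpos = np.array([feats[i].position for i in ci])
        mpos = np.array([mbm.features[j].position for j in mi])
        kpairs, d = _assign_one_kind(cpos, mpos, pair_cutoff)
        for i, j in kpairs:
            pairs.append((ci[i], mi[j]))
            dists.append(float(d[i, j]))
    order = np.argsort([p for p, _ in pairs], kind="stable") if pairs else []
    pairs = [pairs[k] for k in order]
    dists = [dists[k] for k in order]

    n = len(pairs)
    if n == 0:
        rmsd = 0.0
    elif rmsd_mode == "mean":
        rmsd = float(np.mean(dists))
    else:
        rmsd = float(np.sqrt(np.mean(np.square(dists))))
    matched_c = {i for i, _ in pairs}
    matched_m = {j for _, j in pairs}
    return MatchResult(
        n, rmsd, tuple(pairs),
        tuple(i for i in range(len(feats)) if i not in matched_c),
        tuple(j for j in range(len(mbm.features)) if j not in matched_m),
        float(sum(dists)),
    )


# ---------------------------------------------------------------------------
# scoring

def binding_potential(n: int, rmsd: float, params: ScoringParams = ScoringParams()) -> float:
    """BP = n**alpha * max(rmsd, rmsd_floor)**beta;  n = 0 gives BP = 0."""
    if n < 0 or rmsd < 0:
        raise ValueError("n and rmsd must be non-negative")
    if n == 0:
        return 0.0
    r = max(rmsd, params.rmsd_floor)
    return float(n ** params.alpha * r ** params.beta)


def fit_value(bp: float, params: ScoringParams = ScoringParams()) -> float:
    """Sigmoid of log(BP/BP0): exactly BP/(BP + BP0) under the natural-log
    convention; 1/(1 + e**(-log10(BP/BP0))) under base10.  BP = 0 maps to 0."""
    if bp < 0:
        raise ValueError("bp must be >= 0")
    if bp == 0.0:
        return 0.0
    r = bp / params.bp0
    if params.log_convention == "natural":
        return float(r / (1.0 + r))
    return float(1.0 / (1.0 + math.exp(-math.log10(r))))


def screen(
    candidates: list[tuple[str, Pharmacophore]],
    mbm: MBM,
    params: ScoringParams = ScoringParams(),
    pair_cutoff: float = DEFAULT_PAIR_CUTOFF,
) -> list[ScreeningRecord]:
    """Score candidate pharmacophores against the MBM, fit-value descending.

    One record per candidate; ``is_hpt`` is fit_value >= params.threshold
    (inclusive).  An empty candidate list yields an empty report.
    """
    records = []
    for target_id, p in candidates:
        m = match(p, mbm, pair_cutoff, rmsd_mode=params.rmsd_mode)
        bp = binding_potential(m.n, m.rmsd, params)
        fv = fit_value(bp, params)
        records.append(ScreeningRecord(
            target_id, p.source_id, m.n, m.rmsd, bp, fv, fv >= params.threshold))
    records.sort(key=lambda r: (-r.fit_value, r.target_id))
    return records


def screen_fit_values(
    scores: list[tuple[str, float]], params: ScoringParams = ScoringParams()
) -> list[ScreeningRecord]:
    """Build a thresholded report from externally supplied fit values
    (e.g. a published screening table); BP is back-computed from the fit
    under the configured convention, n/RMSD are not available (set to 0)."""
    records = []
    for target_id, fv in scores:
        if not (0 <= fv < 1):
            raise ValueError("fit values must lie in [0, 1)")
        if params.log_convention == "natural":
            bp = 0.0 if fv == 0 else params.bp0 * fv / (1.0 - fv)
        else:
            bp = 0.0 if fv == 0 else params.bp0 * 10 ** (-math.log(1.0 / fv - 1.0))
        records.append(ScreeningRecord(target_id, "", 0, float("nan"), bp, fv,
                                       fv >= params.threshold))
    records.sort(key=lambda r: (-r.fit_value, r.target_id))
    return records


def report_to_dataframe(records: list[ScreeningRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target_id": r.target_id, "structure": r.source_structure,
                "n": r.n, "rmsd": r.rmsd, "bp": r.bp,
                "fit_value": r.fit_value, "is_hpt": r.is_hpt,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# calibration

@dataclass(frozen=True)
class ReciprocalKdLink:
    """Default BP–K_D link:  log10(BP) = 1/K_D - kappa.

    The regression response is 1/K_D = alpha*log10(n) + beta*log10(RMSD) + kappa,
    which is linear in the parameters.  The inverse (for simulation) is
    K_D = 1 / (log10(BP) + kappa), valid only where that quantity is positive.
    """

    def response(self, kd: float) -> float:
        return 1.0 / kd

    def kd_from_bp(self, bp: float, kappa: float) -> float:
        """Inverse link; returns a non-positive number when BP is too small
        for a physical K_D under this reading (caller should skip those)."""
        resp = math.log10(bp) + kappa
        return math.inf if resp == 0 else 1.0 / resp


@dataclass(frozen=True)
class CalibrationResult:
    """Least-squares estimates of the scoring exponents and link constant."""

    alpha: float
    beta: float
    kappa: float
    rss: float  # residual sum of squares on the link scale
    stderr: tuple[float, float, float] | None
    n_obs: int
    params: ScoringParams

    def summary(self) -> str:
        lines = ["BP–K_D calibration (least squares on the link scale)",
                 f"  observations: {self.n_obs}"]
        names = ("alpha", "beta", "kappa")
        for i, name in enumerate(names):
            v = getattr(self, name)
            if self.stderr is not None:
                lines.append(f"  {name:6s} = {v:10.4f}  (se {self.stderr[i]:.4f})")
            else:
                lines.append(f"  {name:6s} = {v:10.4f}")
        lines.append(f"  residual SS = {self.rss:.6g}")
        return "\n".join(lines)


def calibrate(
    observations: list[KdObservation],
    link: ReciprocalKdLink = ReciprocalKdLink(),
    base_params: ScoringParams = ScoringParams(),
) -> CalibrationResult:
    """Fit (alpha, beta, kappa) from (n, RMSD, K_D) observations.

    Regresses the link response on (log10 n, log10 RMSD, 1) by ordinary
    least squares.  Requires >= 3 observations and a full-rank design —
    all-equal n together with all-equal RMSD is unidentifiable.
    """
    if len(observations) < 3:
        raise UnidentifiableError("unidentifiable: need >= 3 observations")
    X = np.array([[math.log10(o.n), math.log10(o.rmsd), 1.0] for o in observations])
    y = np.array([link.response(o.kd) for o in observations])
    if np.linalg.matrix_rank(X, tol=1e-10) < 3:
        raise UnidentifiableError("unidentifiable: rank-deficient design "
                                  "(vary both n and rmsd)")
    coef, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    rss = float(np.sum((y - fitted) ** 2))
    dof = len(observations) - 3
    stderr = None
    if dof > 0:
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        stderr = tuple(float(s) for s in np.sqrt(np.diag(cov)))
    alpha, beta, kappa = (float(c) for c in coef)
    params = replace(base_params, alpha=alpha, beta=beta, kappa=kappa)
    return CalibrationResult(alpha, beta, kappa, rss, stderr, len(observations), params)
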