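"""Maximum-likelihood spatial capture-recapture (SCR) engine.

Implements the full (Poisson-N) SCR likelihood for binary proximity
detectors with a half-normal detection function

    p_jk(x) = g0 · exp(−d(x, trap_j)² / (2σ²)),

supporting a trap-specific behavioural response (bk: detection at a trap
changes g0 at that trap for the rest of the session; traps reset between
sessions because they are moved), 2-class finite-mixture heterogeneity
(h2), and density surfaces that are homogeneous, session-varying, or
log-linear in a habitat covariate.  Activity centers are integrated over
a discretized habitat mask.  Model selection uses AICc with the sample
size equal to the per-session-summed number of detected individuals.

The per-session log-likelihood is

    Σ_i log Σ_x a·D(x)·P(y_i | x) − Λ_s − log n_s!,
    Λ_s = Σ_x a·D(x)·p·(x),

where p·(x) is the probability that an individual centered at x is
detected at least once (computed from the pre-first-capture detection
probabilities, mixture-marginalized when h2 is present).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp

from fragpop.core_data import DetectionData, HabitatMask

logger = logging.getLogger(__name__)


def detect_prob(g0: float, sigma: float, d: np.ndarray | float) -> np.ndarray | float:
    """Half-normal detection probability at distance d from the center."""
    return g0 * np.exp(-np.square(d) / (2.0 * sigma**2))


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SCRModelSpec:
    """Formulae for the three SCR submodels.

    ``density``: ``"~1"``, ``"~session"``, or ``"~<covariate>"`` (log link);
    ``g0``: any of ``"~1"``, ``"~bk"``, ``"~h2"``, ``"~bk+h2"`` (logit link);
    ``sigma`` is always ``"~1"`` (log link).  ``sex`` records which sex's
    data the model is meant for (fits are sex-specific datasets).
    """

    density: str = "~1"
    g0: str = "~1"
    sex: str | None = None

    @property
    def has_bk(self) -> bool:
        return "bk" in self.g0

    @property
    def has_h2(self) -> bool:
        return "h2" in self.g0

    @property
    def density_kind(self) -> str:
        term = self.density.replace("~", "").strip()
        if term in ("1", ""):
            return "intercept"
        if term.lower() in ("session", "y"):
            return "session"
        return "covariate"

    @property
    def covariate(self) -> str | None:
        return (
            self.density.replace("~", "").strip()
            if self.density_kind == "covariate"
            else None
        )

    def label(self) -> str:
        g = self.g0.replace("~", "")
        d = self.density.replace("~", "")
        return f"D(~{d}) g0(~{g}) sigma(~1)"

    def n_parameters(self, n_sessions: int) -> int:
        k = 1  # D intercept
        if self.density_kind == "session":
            k += n_sessions - 1
        elif self.density_kind == "covariate":
            k += 1
        k += 1  # g0 intercept
        if self.has_bk:
            k += 1
        if self.has_h2:
            k += 2  # class-2 offset + mixture logit
        k += 1  # log sigma
        return k


# ---------------------------------------------------------------------------
# Design structure
# ---------------------------------------------------------------------------


@dataclass
class SCRDesign:
    """Sufficient statistics and geometry for likelihood evaluation."""

    spec: SCRModelSpec
    sessions: list[str]
    n_occasions: list[int]
    trap_xy: list[np.ndarray]  # (J_s, 2)
    d2: list[np.ndarray]  # (J_s, X) squared distances to mask points
    # per-session (I_s, J_s) integer count matrices:
    det0: list[np.ndarray]  # detections in pre-capture (b=0) state
    det1: list[np.ndarray]  # detections in post-capture (b=1) state
    nod0: list[np.ndarray]  # non-detections, b=0
    nod1: list[np.ndarray]  # non-detections, b=1
    n_per_session: list[int]
    mask: HabitatMask = field(repr=False, default=None)
    covariate: np.ndarray | None = None

    @property
    def n_histories(self) -> int:
        return int(sum(self.n_per_session))


def bk_indicator(y: np.ndarray) -> np.ndarray:
    """b[i, j, k] = 1 iff individual i was detected at trap j before occasion k
    within the session (persistent, session-reset)."""
    cum = np.cumsum(y, axis=2)
    b = np.zeros_like(y)
    b[:, :, 1:] = (cum[:, :, :-1] > 0).astype(int)
    return b


def build_design(
    data: DetectionData, spec: SCRModelSpec, mask: HabitatMask
) -> SCRDesign:
    """Reduce detection histories to per-trap sufficient statistics.

    With bk, each (individual, trap) contributes four counts: detections
    and non-detections in the pre- and post-first-capture states; without
    bk the post-capture counts are zero.
    """
    if spec.covariate is not None and spec.covariate not in mask.covariates:
        raise ValueError(
            f"density covariate {spec.covariate!r} absent from mask "
            f"(available: {sorted(mask.covariates)})"
        )
    d = data if spec.sex is None else data.filter_sex(spec.sex)
    trap_xy, d2s, det0s, det1s, nod0s, nod1s, ns, occs = [], [], [], [], [], [], [], []
    for s in d.sessions:
        y = d.y[s]
        I, J, K = y.shape
        xy = d.traps[s][["x", "y"]].to_numpy(float)
        d2 = (
            (xy[:, None, 0] - mask.points[None, :, 0]) ** 2
            + (xy[:, None, 1] - mask.points[None, :, 1]) ** 2
        )
        b = bk_indicator(y) if spec.has_bk else np.zeros_like(y)
        det0 = ((y == 1) & (b == 0)).sum(axis=2)
        det1 = ((y == 1) & (b == 1)).sum(axis=2)
        nod0 = ((y == 0) & (b == 0)).sum(axis=2)
        nod1 = ((y == 0) & (b == 1)).sum(axis=2)
        trap_xy.append(xy)
        d2s.append(d2)
        det0s.append(det0)
        det1s.append(det1)
        nod0s.append(nod0)
        nod1s.append(nod1)
        ns.append(I)
        occs.append(K)
    n_recaps = sum(
        int((d.y[s].sum(axis=(1, 2)) > 1).sum()) for s in d.sessions
    )
    if n_recaps == 0:
        logger.warning("no spatial recaptures: sigma is weakly identified")
    cov = mask.covariates[spec.covariate] if spec.covariate else None
    return SCRDesign(
        spec, list(d.sessions), occs, trap_xy, d2s,
        det0s, det1s, nod0s, nod1s, ns, mask, cov,
    )


# ---------------------------------------------------------------------------
# Parameter vector layout
# ---------------------------------------------------------------------------


def _param_names(spec: SCRModelSpec, sessions: list[str]) -> list[str]:
    names = ["D.(Intercept)"]
    if spec.density_kind == "session":
        names += [f"D.session{s}" for s in sessions[1:]]
    elif spec.density_kind == "covariate":
        names += [f"D.{spec.covariate}"]
    names += ["g0.(Intercept)"]
    if spec.has_bk:
        names += ["g0.bk"]
    if spec.has_h2:
        names += ["g0.h2", "pmix.logit"]
    names += ["log(sigma)"]
    return names


def _unpack(beta: np.ndarray, spec: SCRModelSpec, n_sessions: int) -> dict:
    i = 0
    out: dict = {"d0": beta[0]}
    i = 1
    if spec.density_kind == "session":
        out["d_sess"] = np.concatenate([[0.0], beta[i : i + n_sessions - 1]])
        i += n_sessions - 1
    elif spec.density_kind == "covariate":
        out["d_cov"] = beta[i]
        i += 1
    out["g0"] = beta[i]
    i += 1
    out["bk"] = beta[i] if spec.has_bk else 0.0
    if spec.has_bk:
        i += 1
    if spec.has_h2:
        out["h2"] = beta[i]
        out["pmix_logit"] = beta[i + 1]
        i += 2
    out["log_sigma"] = beta[i]
    return out


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

_PENALTY = 1e10


def neg_log_likelihood(beta: np.ndarray, design: SCRDesign) -> float:
    """Negative Poisson-form full log-likelihood (see module docstring)."""
    spec = design.spec
    S = len(design.sessions)
    p = _unpack(np.asarray(beta, float), spec, S)
    sigma = math.exp(p["log_sigma"])
    a = design.mask.cell_area

    # mixture weights and class-specific logit offsets
    if spec.has_h2:
        pi2 = expit(p["pmix_logit"])
        log_phi = np.log(np.array([1.0 - pi2, pi2]))
        class_off = [0.0, p["h2"]]
    else:
        log_phi = np.array([0.0])
        class_off = [0.0]

    total = 0.0
    for s_idx in range(S):
        d2 = design.d2[s_idx]
        K = design.n_occasions[s_idx]
        n_s = design.n_per_session[s_idx]
        hn = np.exp(-d2 / (2.0 * sigma**2))  # (J, X)

        # log density over mask (per km²)
        logD = np.full(d2.shape[1], p["d0"])
        if spec.density_kind == "session":
            logD = logD + p["d_sess"][s_idx]
        elif spec.density_kind == "covariate":
            logD = logD + p["d_cov"] * design.covariate
        logDa = logD + math.log(a)

        per_class_logP = []
        log_surv0 = []  # Σ_j K·log(1−p0) per class, for p·(x)
        for off in class_off:
            g0_0 = expit(p["g0"] + off)
            g0_1 = expit(p["g0"] + p["bk"] + off)
            p0 = np.clip(g0_0 * hn, 1e-300, 1 - 1e-12)
            lp0 = np.log(p0)
            l1m0 = np.log1p(-p0)
            if spec.has_bk:
                p1 = np.clip(g0_1 * hn, 1e-300, 1 - 1e-12)
                lp1 = np.log(p1)
                l1m1 = np.log1p(-p1)
                logP = (
                    design.det0[s_idx] @ lp0
                    + design.nod0[s_idx] @ l1m0
                    + design.det1[s_idx] @ lp1
                    + design.nod1[s_idx] @ l1m1
                )
            else:
                logP = design.det0[s_idx] @ lp0 + design.nod0[s_idx] @ l1m0
            per_class_logP.append(logP)  # (I, X)
            log_surv0.append(K * l1m0.sum(axis=0))  # (X,)

        # Λ_s: expected number of detected individuals
        surv = np.exp(
            logsumexp(np.stack(log_surv0) + log_phi[:, None], axis=0)
        )
        pdot = 1.0 - surv
        lam = float(np.exp(logDa) @ pdot)

        if n_s:
            stack = np.stack(per_class_logP)  # (C, I, X)
            log_mix = logsumexp(stack + log_phi[:, None, None], axis=0)
            log_Li = logsumexp(log_mix + logDa[None, :], axis=1)
            total += float(log_Li.sum())
        total -= lam
        total -= float(gammaln(n_s + 1))

    if not np.isfinite(total):
        logger.debug("non-finite likelihood at beta=%s", beta)
        return _PENALTY
    return -total


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class SCRFit:
    spec: SCRModelSpec
    beta: np.ndarray
    param_names: list[str]
    vcov: np.ndarray
    logLik: float
    K: int
    n_histories: int
    AICc: float
    converged: bool
    design: SCRDesign = field(repr=False, default=None)

    def se(self) -> np.ndarray:
        d = np.diag(self.vcov)
        return np.sqrt(np.where(d > 0, d, np.nan))


def aicc(logLik: float, K: int, n_histories: int) -> float:
    """Small-sample Akaike criterion; n = per-session-summed individuals."""
    n = n_histories
    if n <= K + 1:
        raise ValueError(f"AICc undefined: n={n} <= K+1={K + 1}")
    return -2.0 * logLik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def _default_starts(design: SCRDesign) -> np.ndarray:
    spec = design.spec
    S = len(design.sessions)
    # sigma0: RMS displacement between a recaptured individual's traps
    disps = []
    for s_idx in range(S):
        det = design.det0[s_idx] + design.det1[s_idx]
        xy = design.trap_xy[s_idx]
        for i in range(det.shape[0]):
            js = np.flatnonzero(det[i] > 0)
            if len(js) > 1:
                c = xy[js].mean(axis=0)
                disps.extend(np.linalg.norm(xy[js] - c, axis=1))
    sigma0 = float(np.sqrt(np.mean(np.square(disps)))) if disps else 1.0
    sigma0 = max(sigma0, 0.5)
    # g0: detections per trap-occasion among detected individuals
    tot_det = sum(
        (design.det0[i] + design.det1[i]).sum() for i in range(S)
    )
    tot_cells = sum(
        design.det0[i].shape[0] * design.det0[i].shape[1] * design.n_occasions[i]
        for i in range(S)
    )
    g00 = min(max(tot_det / max(tot_cells, 1), 1e-3), 0.5)
    # D: detected individuals per unit mask area
    d00 = max(design.n_histories / S, 1) / design.mask.total_area

    beta = [math.log(d00)]
    if spec.density_kind == "session":
        beta += [0.0] * (S - 1)
    elif spec.density_kind == "covariate":
        beta += [0.0]
    beta += [math.log(g00 / (1 - g00))]
    if spec.has_bk:
        beta += [0.0]
    if spec.has_h2:
        beta += [0.5, 0.0]
    beta += [math.log(sigma0)]
    return np.array(beta)


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / eps**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * eps**2)
    return H


def fit(
    spec: SCRModelSpec,
    data: DetectionData,
    mask: HabitatMask,
    starts: np.ndarray | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    compute_vcov: bool = True,
) -> SCRFit:
    """Maximize the SCR likelihood by quasi-Newton search.

    Starting values are data-driven (σ from mean recapture displacement,
    D from detected individuals per unit area, g0 from the raw detection
    rate); up to ``n_restarts`` jittered restarts run on failure.  The
    coefficient covariance is the inverse finite-difference Hessian.
    """
    design = build_design(data, spec, mask)
    if design.n_histories == 0:
        raise ValueError(f"no detected individuals for sex={spec.sex!r}")
    x0 = _default_starts(design) if starts is None else np.asarray(starts, float)
    rng = np.random.default_rng(seed)

    best = None
    for attempt in range(n_restarts + 1):
        x_init = x0 if attempt == 0 else x0 + rng.normal(0, 0.3, size=len(x0))
        res = minimize(
            neg_log_likelihood, x_init, args=(design,), method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if res.success and res.fun < _PENALTY / 2:
            best = res if res.fun <= best.fun else best
            break
    converged = bool(best.success and best.fun < _PENALTY / 2)
    if not converged:
        logger.warning("SCR fit did not converge for %s", spec.label())

    K = len(best.x)
    if compute_vcov and converged:
        H = _numeric_hessian(lambda b: neg_log_likelihood(b, design), best.x)
        try:
            vcov = np.linalg.inv(H)
            if not (np.diag(vcov) > 0).all():
                raise np.linalg.LinAlgError("non-PD Hessian")
        except np.linalg.LinAlgError:
            logger.warning("singular Hessian; SEs unavailable")
            vcov = np.full((K, K), np.nan)
    else:
        vcov = np.full((K, K), np.nan)

    logLik = -float(best.fun)
    return SCRFit(
        spec=spec,
        beta=best.x,
        param_names=_param_names(spec, design.sessions),
        vcov=vcov,
        logLik=logLik,
        K=K,
        n_histories=design.n_histories,
        AICc=aicc(logLik, K, design.n_histories),
        converged=converged,
        design=design,
    )


# ---------------------------------------------------------------------------
# Model table
# ---------------------------------------------------------------------------


def model_table(fits: list[SCRFit]) -> pd.DataFrame:
    """AICc ranking with ΔAICc, Akaike weights, and the ≤2-ΔAICc flag."""
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("no converged fits to rank")
    df = pd.DataFrame(
        {
            "model": [f.spec.label() for f in fits],
            "K": [f.K for f in fits],
            "AICc": [f.AICc for f in fits],
            "logLik": [f.logLik for f in fits],
        }
    ).sort_values("AICc", ignore_index=True)
    df["dAICc"] = df["AICc"] - df["AICc"].iloc[0]
    rel = np.exp(-0.5 * df["dAICc"])
    df["weight"] = rel / rel.sum()
    df["competitive"] = df["dAICc"] <= 2.0
    return df[["model", "K", "AICc", "dAICc", "weight", "logLik", "competitive"]]


# ---------------------------------------------------------------------------
# Back-transformed (realized) estimates
# ---------------------------------------------------------------------------


@dataclass
class RealizedEstimates:
    D: tuple[float, float, float]  # point, lower, upper (bears/km²)
    D_se: float
    g0: tuple[float, float, float]
    sigma: tuple[float, float, float]
    N: tuple[float, float, float]
    habitat_area: float
    pmix: float | None = None
    g0_class2: tuple[float, float, float] | None = None
    sex: str | None = None


def _wald(beta: float, se: float) -> tuple[float, float]:
    if not np.isfinite(se):
        return float("nan"), float("nan")
    return beta - 1.96 * se, beta + 1.96 * se


def realized_estimates(
    fit_: SCRFit,
    mask: HabitatMask | None = None,
    habitat_only: bool = True,
    area: float | None = None,
) -> RealizedEstimates:
    """Back-transform link-scale estimates and derive abundance.

    CIs are Wald intervals on the link scale, back-transformed (hence
    asymmetric: lognormal for D and σ, logit-normal for g0).  N = D ×
    habitat area, where the area is the habitat-flagged part of the mask
    (or ``area`` km² when the habitat surface is externally defined).
    """
    if not fit_.converged:
        raise ValueError("cannot derive estimates from a non-converged fit")
    mask = mask if mask is not None else fit_.design.mask
    names = fit_.param_names
    se = fit_.se()
    idx = {n: i for i, n in enumerate(names)}

    b_d = fit_.beta[idx["D.(Intercept)"]]
    se_d = se[idx["D.(Intercept)"]]
    if fit_.spec.density_kind == "session":
        # average realized density across sessions
        effs = [0.0] + [
            fit_.beta[idx[f"D.session{s}"]] for s in fit_.design.sessions[1:]
        ]
        D_pt = float(np.mean([math.exp(b_d + e) for e in effs]))
    elif fit_.spec.density_kind == "covariate":
        cov = fit_.design.covariate
        D_pt = float(np.mean(np.exp(b_d + fit_.beta[idx[f"D.{fit_.spec.covariate}"]] * cov)))
    else:
        D_pt = math.exp(b_d)
    D_ci = (D_pt, D_pt * math.exp(-1.96 * se_d), D_pt * math.exp(1.96 * se_d))
    D_se = D_pt * se_d if np.isfinite(se_d) else float("nan")

    b_g = fit_.beta[idx["g0.(Intercept)"]]
    se_g = se[idx["g0.(Intercept)"]]
    g_lo, g_hi = _wald(b_g, se_g)
    g0_ci = (float(expit(b_g)), float(expit(g_lo)), float(expit(g_hi)))

    b_s = fit_.beta[idx["log(sigma)"]]
    se_s = se[idx["log(sigma)"]]
    s_lo, s_hi = _wald(b_s, se_s)
    sig_ci = (math.exp(b_s), math.exp(s_lo), math.exp(s_hi))

    pmix = None
    g0c2 = None
    if fit_.spec.has_h2:
        pmix = float(expit(fit_.beta[idx["pmix.logit"]]))
        b2 = b_g + fit_.beta[idx["g0.h2"]]
        se2 = math.sqrt(
            fit_.vcov[idx["g0.(Intercept)"], idx["g0.(Intercept)"]]
            + fit_.vcov[idx["g0.h2"], idx["g0.h2"]]
            + 2 * fit_.vcov[idx["g0.(Intercept)"], idx["g0.h2"]]
        ) if np.isfinite(fit_.vcov[0, 0]) else float("nan")
        lo2, hi2 = _wald(b2, se2)
        g0c2 = (float(expit(b2)), float(expit(lo2)), float(expit(hi2)))

    if area is None:
        area = mask.habitat_area() if habitat_only else mask.total_area
    N_ci = tuple(v * area for v in D_ci)
    return RealizedEstimates(
        D=D_ci, D_se=D_se, g0=g0_ci, sigma=sig_ci, N=N_ci,
        habitat_area=float(area), pmix=pmix, g0_class2=g0c2,
        sex=fit_.spec.sex,
    )


def combine_sexes(
    est_f: RealizedEstimates, est_m: RealizedEstimates
) -> tuple[RealizedEstimates, bool]:
    """Sum sex-specific D and N assuming independence.

    Combined SE = √(SE_f² + SE_m²); the combined CI is symmetric normal.
    Returns (combined estimates, female_biased flag from non-overlap of
    the sex-specific 95% CIs).
    """
    if abs(est_f.habitat_area - est_m.habitat_area) > 1e-6:
        raise ValueError("sex-specific estimates use different habitat areas")
    D = est_f.D[0] + est_m.D[0]
    se = math.sqrt(est_f.D_se**2 + est_m.D_se**2)
    D_ci = (D, D - 1.96 * se, D + 1.96 * se)
    area = est_f.habitat_area
    N_ci = tuple(v * area for v in D_ci)
    female_biased = est_f.D[1] > est_m.D[2] or est_m.D[1] > est_f.D[2]
    combined = RealizedEstimates(
        D=D_ci, D_se=se, g0=(float("nan"),) * 3, sigma=(float("nan"),) * 3,
        N=N_ci, habitat_area=area, sex="combined",
    )
    return combined, female_biased


def combine_independent(
    points: list[float], ses: list[float]
) -> tuple[float, float, float, float]:
    """Sum independent estimates: total, SE, and symmetric 95% CI."""
    tot = float(np.sum(points))
    se = float(np.sqrt(np.sum(np.square(ses))))
    return tot, se, tot - 1.96 * se, tot + 1.96 * se


# ---------------------------------------------------------------------------
# Posterior activity centers
# ---------------------------------------------------------------------------


def posterior_activity_centers(
    fit_: SCRFit,
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Per-individual posterior over mask points and its mode.

    π(x | y_i) ∝ D̂(x) · P(y_i | x), mixture-marginalized under h2;
    surfaces are normalized to sum to 1.  Returns (stacked posterior
    array over all sessions' individuals, list of (individual-ish label,
    mode index)); ties break to the lowest mask index with a warning.
    """
    design = fit_.design
    spec = fit_.spec
    p = _unpack(fit_.beta, spec, len(design.sessions))
    sigma = math.exp(p["log_sigma"])
    if spec.has_h2:
        pi2 = expit(p["pmix_logit"])
        log_phi = np.log(np.array([1 - pi2, pi2]))
        class_off = [0.0, p["h2"]]
    else:
        log_phi = np.array([0.0])
        class_off = [0.0]

    posts = []
    modes = []
    for s_idx, sess in enumerate(design.sessions):
        d2 = design.d2[s_idx]
        hn = np.exp(-d2 / (2 * sigma**2))
        logD = np.full(d2.shape[1], p["d0"])
        if spec.density_kind == "session":
            logD = logD + p["d_sess"][s_idx]
        elif spec.density_kind == "covariate":
            logD = logD + p["d_cov"] * design.covariate
        per_class = []
        for off in class_off:
            g0_0 = expit(p["g0"] + off)
            g0_1 = expit(p["g0"] + p["bk"] + off)
            p0 = np.clip(g0_0 * hn, 1e-300, 1 - 1e-12)
            logP = design.det0[s_idx] @ np.log(p0) + design.nod0[s_idx] @ np.log1p(-p0)
            if spec.has_bk:
                p1 = np.clip(g0_1 * hn, 1e-300, 1 - 1e-12)
                logP = (
                    logP
                    + design.det1[s_idx] @ np.log(p1)
                    + design.nod1[s_idx] @ np.log1p(-p1)
                )
            per_class.append(logP)
        log_mix = logsumexp(
            np.stack(per_class) + log_phi[:, None, None], axis=0
        )
        log_post = log_mix + logD[None, :]
        log_post -= logsumexp(log_post, axis=1, keepdims=True)
        post = np.exp(log_post)
        posts.append(post)
        for i in range(post.shape[0]):
            row = post[i]
            mx = row.max()
            tied = np.flatnonzero(row >= mx - 1e-15)
            if len(tied) > 1:
                logger.warning(
                    "posterior mode tie for individual %d in session %s; "
                    "lowest mask index kept", i, sess,
                )
            modes.append((f"{sess}:{i}", int(tied[0])))
    return np.vstack(posts) if posts else np.empty((0, 0)), modes
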