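"""pH- and bile-salt-dependent solubility models and their fitting.

The aqueous solubility of a monoprotic weak acid follows the
Henderson-Hasselbalch relation: the total dissolved concentration is

    S(pH) = S0 * (1 + 10**(pH - pKa))

with ``S0`` the intrinsic (unionized) solubility.  In biorelevant media,
bile-salt micelles solubilize additional drug; the total solubility is the
four-term sum over {aqueous, micellar} x {neutral, ionized} species

    S_tot = BS*S0/C_H2O*K_neutral + S0 + BS*Si/C_H2O*K_ion + Si

with ``Si = S0*10**(pH-pKa)`` the ionized aqueous concentration, ``BS`` the
bile-salt (amphiphile) concentration and ``K = 10**logKmw`` the micelle-water
partition coefficients.  All terms are combined on a single molar basis
(water molarity ``C_H2O`` = 55.5 mol/L) and converted back to mass units.

Fitting follows the derivative-free simplex (Nelder-Mead) scheme with
weighting by the reciprocal of the predicted values; confidence intervals
come from a seeded nonparametric residual bootstrap.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "SolubilityMeasurement",
    "MediumSpec",
    "AqueousSolubilityModel",
    "MicellarPartitionModel",
    "FitResult",
    "MEDIA_REGISTRY",
    "hh_solubility",
    "total_solubility",
    "fit_pka",
    "fit_micellar_partition",
    "UnidentifiableError",
]

WATER_MOLARITY = 55.5  # mol/L, pure water


class UnidentifiableError(ValueError):
    """Raised when the data cannot identify the requested parameters."""


@dataclass(frozen=True)
class SolubilityMeasurement:
    """One equilibrium solubility measurement (mean over replicates)."""

    medium_name: str
    pH_final: float
    solubility: float  # ug/mL
    sd: float = 0.0
    n_replicates: int = 3

    def __post_init__(self):
        if not (0.0 < self.pH_final < 14.0):
            raise ValueError(f"pH_final out of range: {self.pH_final}")
        if self.solubility <= 0:
            raise ValueError("solubility must be > 0")
        if self.n_replicates < 3:
            raise ValueError("n_replicates must be >= 3")


@dataclass(frozen=True)
class MediumSpec:
    """Composition of a dissolution/solubility medium.

    ``buffer_species`` is a list of (pKa, total concentration mM) pairs used
    by the surface-pH model; ``bile_salt_conc`` is the total amphiphile
    concentration in mM.
    """

    name: str
    pH: float
    bile_salt_conc: float = 0.0  # mM
    buffer_species: tuple = ()  # ((pKa, conc_mM), ...)
    buffer_capacity: float | None = None  # mmol/L/dpH, informational
    contains_pepsin: bool = False
    contains_lecithin: bool = False

    def __post_init__(self):
        if self.bile_salt_conc < 0:
            raise ValueError("bile_salt_conc must be >= 0")
        if any(c < 0 for _, c in self.buffer_species):
            raise ValueError("buffer concentrations must be >= 0")


#: Fasted/fed-state simulated fluids and compendial buffers used in the
#: in vitro program.  Compositions from the standard published recipes;
#: override by constructing your own MediumSpec.
MEDIA_REGISTRY: dict[str, MediumSpec] = {
    "FaSSGF_I": MediumSpec("FaSSGF_I", pH=1.6, bile_salt_conc=0.0,
                           buffer_species=()),
    "FaSSGF_III": MediumSpec("FaSSGF_III", pH=1.6, bile_salt_conc=0.08,
                             buffer_species=(), contains_pepsin=True,
                             contains_lecithin=True),
    "acetate_4.5": MediumSpec("acetate_4.5", pH=4.5,
                              buffer_species=((4.76, 29.9),)),
    "FeSSIF_V1_I": MediumSpec("FeSSIF_V1_I", pH=5.0,
                              buffer_species=((4.76, 144.0),)),
    "FeSSIF_V1_II": MediumSpec("FeSSIF_V1_II", pH=5.0, bile_salt_conc=15.0,
                               buffer_species=((4.76, 144.0),),
                               contains_lecithin=True),
    "FaSSIF_V1_II": MediumSpec("FaSSIF_V1_II", pH=6.5, bile_salt_conc=3.0,
                               buffer_species=((7.21, 28.4),),
                               contains_lecithin=True),
    "FaSSIF_V3_I": MediumSpec("FaSSIF_V3_I", pH=6.7, bile_salt_conc=0.0,
                              buffer_species=((6.27, 18.0),),
                              buffer_capacity=5.6),
    "FaSSIF_V3_II": MediumSpec("FaSSIF_V3_II", pH=6.7, bile_salt_conc=3.0,
                               buffer_species=((6.27, 18.0),),
                               buffer_capacity=5.6, contains_lecithin=True),
    "phosphate_6.5": MediumSpec("phosphate_6.5", pH=6.5,
                                buffer_species=((7.21, 50.0),),
                                buffer_capacity=18.5),
    "phosphate_6.8": MediumSpec("phosphate_6.8", pH=6.8,
                                buffer_species=((7.21, 50.0),),
                                buffer_capacity=25.0),
}


@dataclass
class AqueousSolubilityModel:
    """Henderson-Hasselbalch model of a monoprotic weak acid."""

    S0: float  # intrinsic solubility, ug/mL
    pKa: float
    MW: float = 244.3  # g/mol, used for molar conversions

    def __post_init__(self):
        if self.S0 <= 0:
            raise ValueError("S0 must be > 0")


@dataclass
class MicellarPartitionModel:
    """Micelle-water partitioning of neutral and ionized species."""

    logKmw_neutral: float
    logKmw_ion: float
    C_H2O: float = WATER_MOLARITY

    def __post_init__(self):
        if self.logKmw_neutral < self.logKmw_ion:
            raise ValueError(
                "neutral-species partitioning must be >= ionized-species")


@dataclass
class FitResult:
    """Point estimates with bootstrap confidence intervals."""

    params: dict[str, float]
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    sse: float = np.nan
    r2: float = np.nan
    n_boot: int = 0


def hh_solubility(pH, model: AqueousSolubilityModel):
    """Total (neutral + ionized) aqueous solubility in ug/mL at ``pH``."""
    pH = np.asarray(pH, dtype=float)
    if not np.all(np.isfinite(pH)):
        raise ValueError("pH must be finite")
    out = model.S0 * (1.0 + 10.0 ** (pH - model.pKa))
    return out if out.ndim else float(out)


def total_solubility(pH, bile_salt_conc, aq: AqueousSolubilityModel,
                     mic: MicellarPartitionModel):
    """Total solubility (ug/mL) including micellar solubilization.

    ``bile_salt_conc`` in mM.  All four terms are evaluated in mol/L and the
    sum converted back to ug/mL; at zero bile salt this reduces exactly to
    :func:`hh_solubility`.
    """
    pH = np.asarray(pH, dtype=float)
    bs = np.asarray(bile_salt_conc, dtype=float)
    if np.any(bs < 0):
        raise ValueError("bile_salt_conc must be >= 0")
    s0 = aq.S0 * 1e-3 / aq.MW          # mol/L
    si = s0 * 10.0 ** (pH - aq.pKa)    # ionized species, mol/L
    bsm = bs * 1e-3                    # mol/L
    tot = (bsm * s0 / mic.C_H2O * 10.0 ** mic.logKmw_neutral
           + s0
           + bsm * si / mic.C_H2O * 10.0 ** mic.logKmw_ion
           + si)
    out = tot * aq.MW * 1e3            # back to ug/mL
    return out if out.ndim else float(out)


def _weighted_sse(obs, pred):
    # reciprocal-of-predicted weighting on squared residuals
    pred = np.maximum(pred, 1e-12)
    return float(np.sum((obs - pred) ** 2 / pred))


def _nm(fun, x0, **kw):
    return minimize(fun, x0, method="Nelder-Mead",
                    options=dict(xatol=1e-9, fatol=1e-12, maxiter=4000, **kw))


def fit_pka(measurements: list[SolubilityMeasurement],
            S0_fixed: float | None = None, n_boot: int = 1000,
            seed: int = 0) -> FitResult:
    """Fit pKa to aqueous-buffer solubilities with S0 fixed.

    S0 defaults to the minimum observed solubility (taken to represent the
    intrinsic solubility).  The fit minimizes the 1/predicted-weighted SSE
    with a Nelder-Mead simplex, parameterized in pKa directly (predictions
    are formed in log-ratio space to avoid overflow at high pH).
    """
    if len(measurements) < 3:
        raise UnidentifiableError("need >= 3 aqueous measurements")
    ph = np.array([m.pH_final for m in measurements])
    sol = np.array([m.solubility for m in measurements])
    if np.ptp(ph) < 2.0 or len(np.unique(ph)) < 2:
        raise UnidentifiableError("pH range too narrow to identify pKa")
    s0 = float(np.min(sol)) if S0_fixed is None else float(S0_fixed)
    if np.ptp(sol) / s0 < 0.05:
        raise UnidentifiableError(
            "no ionization regime sampled: all solubilities at S0")

    def predict(pka):
        # log10(S/S0 - 1) = pH - pKa; evaluate stably
        return s0 * (1.0 + 10.0 ** np.clip(ph - pka, -30, 30))

    def obj(x):
        return _weighted_sse(sol, predict(x[0]))

    res = _nm(obj, [float(np.median(ph))])
    pka = float(res.x[0])
    pred = predict(pka)
    r2 = 1.0 - np.sum((sol - pred) ** 2) / np.sum((sol - np.mean(sol)) ** 2)
    ci = {}
    if n_boot:
        rng = np.random.default_rng(seed)
        resid = (sol - pred) / pred  # relative residuals
        est = []
        for _ in range(n_boot):
            synth = pred * (1.0 + rng.choice(resid, size=resid.size))
            r = _nm(lambda x: _weighted_sse(synth, predict(x[0])), [pka])
            est.append(r.x[0])
        lo, hi = np.percentile(est, [2.5, 97.5])
        ci["pKa"] = (float(lo), float(hi))
    return FitResult({"pKa": pka, "S0": s0}, ci, sse=res.fun, r2=float(r2),
                     n_boot=n_boot)


def fit_micellar_partition(measurements: list[SolubilityMeasurement],
                           media: list[MediumSpec],
                           aq: AqueousSolubilityModel,
                           n_boot: int = 1000, seed: int = 0) -> FitResult:
    """Fit (logKmw_neutral, logKmw_ion) to biorelevant solubilities.

    ``media[i]`` supplies the bile-salt concentration for ``measurements[i]``;
    the aqueous model (S0, pKa) is held fixed.  Deterministic multi-start
    Nelder-Mead on the 1/predicted-weighted SSE.
    """
    if len(measurements) != len(media):
        raise ValueError("one medium per measurement required")
    bs = np.array([m.bile_salt_conc for m in media])
    if not np.any(bs > 0):
        raise UnidentifiableError("all media bile-salt free")
    ph = np.array([m.pH_final for m in measurements])
    sol = np.array([m.solubility for m in measurements])

    aq_pred = hh_solubility(ph, aq)
    if np.all(sol[bs > 0] <= aq_pred[bs > 0] * 1.001):
        warnings.warn("no micellar solubility excess; partition estimates "
                      "collapse toward the lower bound", stacklevel=2)

    def predict(lkn, lki):
        mic = MicellarPartitionModel.__new__(MicellarPartitionModel)
        mic.logKmw_neutral, mic.logKmw_ion, mic.C_H2O = lkn, lki, WATER_MOLARITY
        return total_solubility(ph, bs, aq, mic)

    def obj(x):
        return _weighted_sse(sol, predict(x[0], x[1]))

    best = None
    for start in [(5.0, 2.5), (5.5, 3.0), (4.5, 2.0), (6.0, 1.5), (4.0, 3.5)]:
        r = _nm(obj, list(start))
        if best is None or r.fun < best.fun:
            best = r
    lkn, lki = (float(best.x[0]), float(best.x[1]))
    if lkn < lki:  # enforce the amphiphile-partitioning ordering
        lkn, lki = lki, lkn
    pred = predict(lkn, lki)
    r2 = 1.0 - np.sum((sol - pred) ** 2) / np.sum((sol - np.mean(sol)) ** 2)
    ci = {}
    if n_boot:
        rng = np.random.default_rng(seed)
        resid = (sol - pred) / pred
        e_n, e_i = [], []
        for _ in range(n_boot):
            synth = pred * (1.0 + rng.choice(resid, size=resid.size))
            r = _nm(lambda x: _weighted_sse(synth, predict(x[0], x[1])),
                    [lkn, lki])
            e_n.append(r.x[0]); e_i.append(r.x[1])
        ci["logKmw_neutral"] = tuple(np.percentile(e_n, [2.5, 97.5]))
        ci["logKmw_ion"] = tuple(np.percentile(e_i, [2.5, 97.5]))
    return FitResult({"logKmw_neutral": lkn, "logKmw_ion": lki}, ci,
                     sse=best.fun, r2=float(r2), n_boot=n_boot)
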