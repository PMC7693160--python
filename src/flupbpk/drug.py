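"""Drug model container and the default flurbiprofen parameter set.

Flurbiprofen is a BCS class II monoprotic weak acid (pKa 4.05, logP 3.99)
that is almost completely absorbed, very highly protein bound (fu 0.01),
and cleared predominantly by hepatic CYP2C9 oxidation (fm ~= 0.71) with minor
UGT2B7/UGT1A9 glucuronidation and a small renal component.  The parameter set
below carries the in vitro solubility/partitioning estimates, the
allele-specific CYP2C9 Michaelis-Menten kinetics (with the heterozygote Vmax
scaled by the clinically observed clearance ratios), IVIVE scaling factors,
and the effect-compartment pharmacodynamic parameters for the two analgesia
endpoints (tooth-pulp evoked potentials and subjective pain rating).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .media import AqueousSolubilityModel, MicellarPartitionModel

__all__ = ["CypKinetics", "UgtKinetics", "Formulation", "PDParams",
           "DrugModel", "flurbiprofen", "GENOTYPES"]

GENOTYPES = ("1*/1*", "1*/2*", "1*/3*", "2*/2*", "2*/3*", "3*/3*")


@dataclass(frozen=True)
class CypKinetics:
    """Recombinant-enzyme Michaelis-Menten pair, fu,mic-normalized."""

    vmax: float  # pmol/min/pmol CYP
    km: float    # uM


@dataclass(frozen=True)
class UgtKinetics:
    vmax: float  # pmol/min/mg microsomal protein
    km: float    # uM


@dataclass(frozen=True)
class PDParams:
    """Effect-compartment inhibitory Emax parameters for one endpoint."""

    keo: float        # 1/h
    ic50: float       # mg/L
    keo_cv: float     # fractional CV for inter-individual variability
    ic50_cv: float
    baseline: float = 100.0
    endpoint: str = "TPEP"

    def __post_init__(self):
        if self.keo <= 0 or self.ic50 <= 0:
            raise ValueError("keo and IC50 must be > 0")


@dataclass(frozen=True)
class Formulation:
    """Oral dosage-form inputs for the mechanistic absorption model.

    ``kind`` is 'solution' (entire dose pre-dissolved in the stomach) or
    'IR_tablet'.  ``psd_radius_um`` is the volume-median particle radius and
    ``psd_sigma_g`` the geometric SD of the lognormal size distribution
    (``psd_nbins`` equal-volume bins); the fitted dissolution scalars are
    conditional on this PSD.
    """

    kind: str = "IR_tablet"
    s_dlm_stomach: float = 0.001
    s_dlm_si: float = 0.125
    kd: float | None = None       # 1/h first-order disintegration
    t_lag: float = 0.0            # h
    psd_radius_um: float = 7.0
    psd_sigma_g: float = 2.0
    psd_nbins: int = 5

    def particle_bins(self):
        """(radii_cm, volume_fractions) of the discretized PSD."""
        if self.kind == "solution":
            return np.array([]), np.array([])
        n = self.psd_nbins
        if n == 1 or self.psd_sigma_g <= 1.0:
            return (np.array([self.psd_radius_um * 1e-4]), np.array([1.0]))
        from scipy.stats import norm
        q = (np.arange(n) + 0.5) / n
        z = norm.ppf(q)
        radii = self.psd_radius_um * 1e-4 * self.psd_sigma_g ** z
        return radii, np.full(n, 1.0 / n)


@dataclass
class DrugModel:
    """Complete physicochemical / ADME / PD input set for one compound."""

    name: str
    mw: float                 # g/mol
    logp: float
    pka: float
    acid_base: str            # 'acid' | 'base' | 'neutral'
    bp_ratio: float           # blood:plasma
    fu: float                 # fraction unbound in plasma
    peff: float               # human jejunal effective permeability, cm/s
    aqueous: AqueousSolubilityModel
    micellar: MicellarPartitionModel
    formulation: Formulation
    cyp2c9: dict[str, CypKinetics]
    isef: float
    ugt: dict[str, UgtKinetics]
    additional_hlm_clint: float   # uL/min/mg microsomal protein
    cl_renal: float               # L/h, plasma clearance
    kp_scalar: float = 1.0
    diffusion_coeff: float = 7e-6  # cm^2/s in luminal fluid
    true_density: float = 1.2      # g/cm^3
    pd: dict[str, PDParams] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 < self.fu <= 1.0):
            raise ValueError("fu must be in (0, 1]")
        for g, k in self.cyp2c9.items():
            if k.vmax <= 0 or k.km <= 0:
                raise ValueError(f"non-positive CYP kinetics for {g}")

    @property
    def fu_blood(self) -> float:
        return self.fu / self.bp_ratio

    def with_formulation(self, **kw) -> "DrugModel":
        return replace(self, formulation=replace(self.formulation, **kw))


def genotype_vmax(wild_type_vmax: float, cl_ratio: float) -> float:
    """Scale the wild-type Vmax by a clinically observed clearance ratio.

    Used for heterozygotes whose in vitro kinetics are unavailable: the Km is
    kept at the wild-type value and Vmax is reduced proportionally to the
    observed clearance fraction (0 < ratio <= 1).
    """
    if not (0.0 < cl_ratio <= 1.0):
        raise ValueError("cl_ratio must be in (0, 1]")
    return wild_type_vmax * cl_ratio


def flurbiprofen() -> DrugModel:
    """Default flurbiprofen model (racemate, immediate-release oral)."""
    wt = CypKinetics(15.79, 8.756)
    v22, v33 = CypKinetics(10.04, 10.39), CypKinetics(8.901, 23.25)
    cyp = {
        "1*/1*": wt,
        "1*/2*": CypKinetics(genotype_vmax(wt.vmax, 0.73), wt.km),
        "1*/3*": CypKinetics(genotype_vmax(wt.vmax, 0.605), wt.km),
        "2*/2*": v22,
        # 2*/3* kinetics are not measured; lumped mean of the homozygote pairs
        "2*/3*": CypKinetics(0.5 * (v22.vmax + v33.vmax),
                             0.5 * (v22.km + v33.km)),
        "3*/3*": v33,
    }
    return DrugModel(
        name="flurbiprofen",
        mw=244.3, logp=3.99, pka=4.05, acid_base="acid",
        bp_ratio=0.55, fu=0.01, peff=4.83e-4,
        aqueous=AqueousSolubilityModel(S0=18.1, pKa=4.05, MW=244.3),
        micellar=MicellarPartitionModel(logKmw_neutral=5.36, logKmw_ion=2.56),
        formulation=Formulation(),
        cyp2c9=cyp, isef=0.3,
        ugt={"UGT2B7": UgtKinetics(119.7, 50.21),
             "UGT1A9": UgtKinetics(3.286, 182.2)},
        additional_hlm_clint=7.88,
        cl_renal=0.066,
        kp_scalar=0.7,
        pd={"TPEP": PDParams(keo=0.56, ic50=25.8, keo_cv=0.43, ic50_cv=0.21,
                             endpoint="TPEP"),
            "pain_rating": PDParams(keo=0.89, ic50=27.6, keo_cv=0.24,
                                    ic50_cv=0.10, endpoint="pain_rating")},
    )
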