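"""The FGF/VEGF -> MAPK signaling model.

Network topology
----------------
FGF arm: FGF binds cell-surface heparan sulfate (HSGAG) and, competitively
and non-productively, free FGFR1. Only the FGF:HSGAG complex recruits FGFR1
into the signaling-competent ternary complex; ternary complexes dimerize and
trans-autophosphorylate, and the active dimer binds and phosphorylates FRS2.
pFRS2 phosphorylates MEK at two sites. Doubly phosphorylated ERK (ppERK)
feeds back by driving ubiquitination of FRS2/pFRS2 (FRS2u), which makes the
FGF-driven ERK response transient.

VEGF arm: VEGF binding to VEGFR2 is lumped with receptor autophosphorylation
into one reversible step (pR2). pR2 recruits Grb2:Sos either directly or via
phosphorylated Shc; Sos loads Ras with GTP, Ras-GTP activates Raf (aRaf),
and aRaf phosphorylates MEK at two sites. GAP and a slow intrinsic
hydrolysis return Ras-GTP to Ras.

Shared MAPK core: ppMEK phosphorylates ERK at two sites. Ptase2
dephosphorylates pMEK/ppMEK (association rate ``k_dpMEK_p``, catalytic rate
``ked2`` for the doubly phosphorylated form), Ptase3 dephosphorylates
pERK/ppERK, and Ptase1 is a generic phosphatase for pFRS2, pShc and aRaf.

Trafficking: free and bound receptor forms internalize, recycle, and are
degraded into explicit degraded-pool species so that receptor moieties stay
conserved. All bound FGFR1 forms share one trafficking rate set; VEGFR2 has
its own six rates (k_intf/k_intb, k_recf/k_recb, k_degf/k_degb).

The model covers a two-hour stimulation window; no ligand or protein
synthesis/turnover is included apart from the ubiquitination and
degraded-pool transfers above.

The reaction table itself is a reconstruction assembled from the published
network description (the original tabular supplement is not redistributed
here); it is engineered to the declared structural size of the published
model: 70 reactions, 72 species, 75 rate constants, with the heparin
extension adding exactly 26 reactions, 25 species, and 3 rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import ReactionNetwork, Reaction, Species, NetworkConfigError

MAIN_COUNTS = {"reactions": 70, "species": 72, "parameters": 75}
HEPARIN_EXTRA = {"reactions": 26, "species": 25, "parameters": 3}

# molecular weights (g/mol) fixing the ng/ml <-> nM dose conversions
LIGAND_MW = {"FGF": 25_000.0, "VEGF": 45_455.0, "heparin": 15_000.0}


@dataclass
class LigandSpec:
    name: str
    molecular_weight: float

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise ValueError("molecular weight must be positive")


def ligand_unit_convert(value: float, from_unit: str, ligand: str | LigandSpec) -> float:
    """Convert ligand doses between ng/ml and nM.

    nM = (ng/ml) * 1000 / MW  (MW in g/mol).
    """
    if value < 0:
        raise ValueError("dose must be non-negative")
    if isinstance(ligand, LigandSpec):
        mw = ligand.molecular_weight
    else:
        try:
            mw = LIGAND_MW[ligand]
        except KeyError:
            raise ValueError(f"unknown ligand {ligand!r}")
    if from_unit == "ng_per_ml":
        return value * 1000.0 / mw
    if from_unit == "nM":
        return value * mw / 1000.0
    raise ValueError(f"unknown unit {from_unit!r}")


@dataclass
class TraffickingRates:
    receptor: str
    k_intf: float
    k_intb: float
    k_recf: float
    k_recb: float
    k_degf: float
    k_degb: float

    def __post_init__(self):
        for name in ("k_intf", "k_intb", "k_recf", "k_recb", "k_degf", "k_degb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SignalingModel:
    network: ReactionNetwork
    arm_tags: dict[str, str] = field(default_factory=dict)
    readout_defs: dict[str, list[str]] = field(default_factory=dict)
    free_rate_constants: list[str] = field(default_factory=list)
    free_initial_amounts: list[str] = field(default_factory=list)

    @property
    def free_quantities(self) -> list[str]:
        """The names optimized during calibration: rate constants plus
        ``init:<species>`` entries for fitted initial amounts."""
        return list(self.free_rate_constants) + [
            f"init:{s}" for s in self.free_initial_amounts
        ]

    def fgfr1_trafficking(self) -> TraffickingRates:
        p = self.network.parameters
        return TraffickingRates(
            "FGFR1", p["k_intf_R1"], p["k_intb_R1"], p["k_recf_R1"],
            p["k_recb_R1"], p["k_degf_R1"], p["k_degb_R1"],
        )

    def vegfr2_trafficking(self) -> TraffickingRates:
        p = self.network.parameters
        return TraffickingRates(
            "VEGFR2", p["k_intf"], p["k_intb"], p["k_recf"],
            p["k_recb"], p["k_degf"], p["k_degb"],
        )


# ---------------------------------------------------------------------------
# Baseline quantitative scenario.
#
# Receptor and HSGAG densities come from the published cell-level numbers
# (FGFR1 2e4, VEGFR2 1e3, HSGAG 1e5 molecules/cell). Rate constants are set
# at literature-typical magnitudes for ligand-receptor binding
# (~1e7 /M/s ~ 0.6 /nM/min), membrane/cytosolic protein association, and
# kinase/phosphatase turnover, then calibrated once so the documented
# behaviors of the published model hold at baseline (biphasic FGF dose
# response; FGF >> VEGF pERK output at equimolar doses with fast VEGFR2
# trafficking; fast transient FGF response vs slower VEGF response).
# Time unit: minutes.
# ---------------------------------------------------------------------------

BASELINE_PARAMETERS: dict[str, float] = {
    # FGF binding and receptor activation
    "kf_fgf_hsgag": 0.5,      # /nM/min
    "kr_fgf_hsgag": 0.125,      # /min  (Kd 1 nM)
    "kf_fgf_fgfr1": 0.5,      # /nM/min
    "kr_fgf_fgfr1": 0.25,      # /min  (Kd 2 nM, ~2x weaker than FGF:HSGAG)
    "kf_fhr": 2.5e-06,           # /(molec/cell)/min, FGF:HSGAG + FGFR1
    "kr_fhr": 0.1,
    "kf_dim": 0.003,           # ternary-complex dimerization
    "kr_dim": 0.02,
    "k_pR1": 5.0,             # dimer trans-autophosphorylation
    "k_dpR1": 0.1,
    # FRS2 activation and feedback
    "kf_frs2_bind": 0.003,
    "kr_frs2_bind": 0.1,
    "kc_frs2_phos": 10.0,
    "kf_ptase1_pfrs2": 1e-6,
    "kr_ptase1_pfrs2": 0.1,
    "kc_ptase1_pfrs2": 1.0,
    "kf_fb": 5e-05,            # ppERK binding FRS2/pFRS2
    "kr_fb": 0.1,
    "kc_ub": 12.0,             # ubiquitination under ppERK feedback
    # FGFR1 trafficking (slow relative to VEGFR2)
    "k_intf_R1": 0.005,
    "k_recf_R1": 0.05,
    "k_degf_R1": 0.005,
    "k_intb_R1": 0.01,
    "k_recb_R1": 0.05,
    "k_degb_R1": 0.01,
    # VEGFR2 binding/autophosphorylation and trafficking (fast)
    "k_pR2": 0.4,             # /nM/min
    "k_dpR2": 0.05,
    "k_intf": 0.05,
    "k_recf": 0.2,
    "k_degf": 0.05,
    "k_intb": 0.15,
    "k_recb": 0.15,
    "k_degb": 0.08,
    # Shc / Grb2:Sos / Ras
    "kf_shc": 1e-5,
    "kr_shc": 0.1,
    "kc_shc": 5.0,
    "kf_ptase1_shc": 1e-5,    # fast pShc turnover keeps Ras loading
    "kr_ptase1_shc": 0.1,     # proportional to receptor occupancy
    "kc_ptase1_shc": 5.0,
    "kf_grb_sos": 1e-6,       # Sos joining Grb2 (free or docked)
    "kr_grb_sos": 0.1,
    "kf_gs_dock": 2e-05,       # preformed Grb2:Sos docking on pShc/pR2
    "kr_gs_dock": 1.0,
    "kf_grb_dock": 2e-06,      # Grb2 alone docking on pShc/pR2
    "kr_grb_dock": 1.0,
    "kf_sos_ras": 0.001,
    "kr_sos_ras": 0.1,
    "kc_sos_ras": 40.0,
    "kf_gap": 1e-05,
    "kr_gap": 0.1,
    "kc_gap": 5.0,
    "k_iRas": 0.02,           # intrinsic Ras-GTP hydrolysis
    # Raf activation/deactivation
    "kf_rasgtp_raf": 5e-05,
    "kr_rasgtp_raf": 0.1,
    "kc_raf_act": 5.0,
    "kf_ptase1_araf": 1e-05,
    "kr_ptase1_araf": 0.1,
    "kc_ptase1_araf": 3.0,
    # MEK phosphorylation (two sites, per kinase)
    "kf_pfrs2_mek": 2e-4,
    "kr_pfrs2_mek": 1.0,
    "kc_pfrs2_mek": 100.0,
    "kf_araf_mek": 2e-05,
    "kr_araf_mek": 1.0,
    "kc_araf_mek": 6.0,
    # MEK dephosphorylation by Ptase2
    "k_dpMEK_p": 0.03,        # association of pMEK/ppMEK with Ptase2
    "k_dpMEK_m": 0.1,
    "ked1": 5.0,              # catalytic, Ptase2:pMEK -> MEK
    "ked2": 5.0,              # catalytic, Ptase2:ppMEK -> pMEK
    # ERK phosphorylation by ppMEK (both sites share kinetics)
    "kf_mek_erk": 2e-05,
    "kr_mek_erk": 0.1,
    "kc_mek_erk": 5.0,
    # ERK dephosphorylation by Ptase3
    "kf_ptase3": 1e-05,
    "kr_ptase3": 0.1,
    "kc_ptase3_1": 3.0,
    "kc_ptase3_2": 3.0,
}

BASELINE_INITIAL_AMOUNTS: dict[str, float] = {
    "HSGAG": 1e5,
    "FGFR1": 2e4,
    "VEGFR2": 1e3,
    "FRS2": 1e4,
    "Ptase1": 1e5,
    "Shc": 1e5,
    "Grb2": 1e5,
    "Sos": 2e4,
    "GAP": 5e4,
    "Ras": 2e4,
    "Raf": 3e5,
    "MEK": 6e5,
    "Ptase2": 5e4,
    "ERK": 2e6,
    "Ptase3": 1e5,
}

#: rate constants estimated during calibration (overlapping MAPK kinetics,
#: the VEGF/Ras/Raf interface, and the six VEGFR2 trafficking rates)
FREE_RATE_CONSTANTS: list[str] = [
    # shared MAPK core (20)
    "kf_pfrs2_mek", "kr_pfrs2_mek", "kc_pfrs2_mek",
    "kf_araf_mek", "kr_araf_mek", "kc_araf_mek",
    "k_dpMEK_p", "k_dpMEK_m", "ked1", "ked2",
    "kf_mek_erk", "kr_mek_erk", "kc_mek_erk",
    "kf_ptase3", "kr_ptase3", "kc_ptase3_1", "kc_ptase3_2",
    "kf_ptase1_araf", "kr_ptase1_araf", "kc_ptase1_araf",
    # VEGFR2 trafficking (6)
    "k_intf", "k_recf", "k_degf", "k_intb", "k_recb", "k_degb",
    # VEGFR2 activation and Ras/Raf interface (8)
    "k_pR2", "k_dpR2", "kf_rasgtp_raf", "kr_rasgtp_raf", "kc_raf_act",
    "kc_sos_ras", "kc_gap", "k_iRas",
]

#: initial amounts estimated during calibration (the sensitivity-influential
#: pathway intermediates)
FREE_INITIAL_AMOUNTS: list[str] = ["FRS2", "Ptase2", "Ras", "MEK", "ERK"]

N_FREE_QUANTITIES = len(FREE_RATE_CONSTANTS) + len(FREE_INITIAL_AMOUNTS)  # 39


def _species_table() -> list[Species]:
    E, S, I, D = "extracellular", "surface", "internal", "degraded_pool"
    init = BASELINE_INITIAL_AMOUNTS
    rows: list[tuple[str, str]] = [
        # ligands (clamped; doses set by the stimulation protocol)
        ("FGF", E), ("VEGF", E),
        # FGF arm, surface
        ("HSGAG", S), ("FGFR1", S), ("FGF_HSGAG", S), ("FGF_FGFR1", S),
        ("FHR", S), ("FHR2", S), ("pFHR2", S),
        # FGFR1 trafficking pools
        ("FGFR1_i", I), ("FGFR1_deg", D),
        ("FGF_FGFR1_i", I), ("FGF_FGFR1_deg", D),
        ("FHR_i", I), ("FHR_deg", D),
        ("FHR2_i", I), ("FHR2_deg", D),
        ("pFHR2_i", I), ("pFHR2_deg", D),
        # FRS2 module
        ("FRS2", I), ("pFHR2_FRS2", S), ("pFRS2", I), ("FRS2u", I),
        ("ppERK_pFRS2", I), ("ppERK_FRS2", I),
        ("Ptase1", I), ("Ptase1_pFRS2", I), ("Ptase1_pShc", I),
        ("Ptase1_aRaf", I),
        # VEGFR2 and trafficking
        ("VEGFR2", S), ("pR2", S),
        ("VEGFR2_i", I), ("VEGFR2_deg", D), ("pR2_i", I), ("pR2_deg", D),
        # adapters and Ras
        ("Shc", I), ("pR2_Shc", S), ("pShc", I),
        ("Grb2", I), ("Sos", I), ("Grb2_Sos", I),
        ("pShc_Grb2", I), ("pShc_Grb2Sos", I),
        ("pR2_Grb2", S), ("pR2_Grb2Sos", S),
        ("Ras", I), ("pShcGrb2Sos_Ras", I), ("pR2Grb2Sos_Ras", S),
        ("RasGTP", I), ("GAP", I), ("GAP_RasGTP", I),
        # Raf
        ("Raf", I), ("RasGTP_Raf", I), ("aRaf", I),
        # MEK module
        ("MEK", I), ("pMEK", I), ("ppMEK", I),
        ("pFRS2_MEK", I), ("pFRS2_pMEK", I),
        ("aRaf_MEK", I), ("aRaf_pMEK", I),
        ("Ptase2", I), ("Ptase2_pMEK", I), ("Ptase2_ppMEK", I),
        # ERK module
        ("ERK", I), ("pERK", I), ("ppERK", I),
        ("ppMEK_ERK", I), ("ppMEK_pERK", I),
        ("Ptase3", I), ("Ptase3_pERK", I), ("Ptase3_ppERK", I),
    ]
    return [
        Species(name, comp, init.get(name, 0.0), clamped=(comp == E))
        for name, comp in rows
    ]


def _reaction_table() -> list[tuple[Reaction, str]]:
    """The 70 reactions with their arm tags."""
    R = Reaction
    rows: list[tuple[Reaction, str]] = []

    def add(tag, label, reactants, products, kf, kr=None):
        rows.append((R(label, reactants, products, kf, kr), tag))

    F, V, M, T = "FGF_arm", "VEGF_arm", "shared_MAPK", "trafficking"

    # --- FGF binding and receptor activation (R1-R5)
    add(F, "R1", [("FGF", 1), ("HSGAG", 1)], [("FGF_HSGAG", 1)],
        "kf_fgf_hsgag", "kr_fgf_hsgag")
    add(F, "R2", [("FGF", 1), ("FGFR1", 1)], [("FGF_FGFR1", 1)],
        "kf_fgf_fgfr1", "kr_fgf_fgfr1")
    add(F, "R3", [("FGF_HSGAG", 1), ("FGFR1", 1)], [("FHR", 1)],
        "kf_fhr", "kr_fhr")
    add(F, "R4", [("FHR", 2)], [("FHR2", 1)], "kf_dim", "kr_dim")
    add(F, "R5", [("FHR2", 1)], [("pFHR2", 1)], "k_pR1", "k_dpR1")
    # --- FRS2 activation and ppERK feedback (R6-R13)
    add(F, "R6", [("pFHR2", 1), ("FRS2", 1)], [("pFHR2_FRS2", 1)],
        "kf_frs2_bind", "kr_frs2_bind")
    add(F, "R7", [("pFHR2_FRS2", 1)], [("pFHR2", 1), ("pFRS2", 1)],
        "kc_frs2_phos")
    add(F, "R8", [("pFRS2", 1), ("Ptase1", 1)], [("Ptase1_pFRS2", 1)],
        "kf_ptase1_pfrs2", "kr_ptase1_pfrs2")
    add(F, "R9", [("Ptase1_pFRS2", 1)], [("Ptase1", 1), ("FRS2", 1)],
        "kc_ptase1_pfrs2")
    add(F, "R10", [("ppERK", 1), ("pFRS2", 1)], [("ppERK_pFRS2", 1)],
        "kf_fb", "kr_fb")
    add(F, "R11", [("ppERK_pFRS2", 1)], [("ppERK", 1), ("FRS2u", 1)], "kc_ub")
    add(F, "R12", [("ppERK", 1), ("FRS2", 1)], [("ppERK_FRS2", 1)],
        "kf_fb", "kr_fb")
    add(F, "R13", [("ppERK_FRS2", 1)], [("ppERK", 1), ("FRS2u", 1)], "kc_ub")
    # --- FGFR1 trafficking (R14-R23); all bound forms share one rate set
    add(T, "R14", [("FGFR1", 1)], [("FGFR1_i", 1)], "k_intf_R1", "k_recf_R1")
    add(T, "R15", [("FGFR1_i", 1)], [("FGFR1_deg", 1)], "k_degf_R1")
    add(T, "R16", [("FGF_FGFR1", 1)], [("FGF_FGFR1_i", 1)],
        "k_intb_R1", "k_recb_R1")
    add(T, "R17", [("FGF_FGFR1_i", 1)], [("FGF_FGFR1_deg", 1)], "k_degb_R1")
    add(T, "R18", [("FHR", 1)], [("FHR_i", 1)], "k_intb_R1", "k_recb_R1")
    add(T, "R19", [("FHR_i", 1)], [("FHR_deg", 1)], "k_degb_R1")
    add(T, "R20", [("FHR2", 1)], [("FHR2_i", 1)], "k_intb_R1", "k_recb_R1")
    add(T, "R21", [("FHR2_i", 1)], [("FHR2_deg", 1)], "k_degb_R1")
    add(T, "R22", [("pFHR2", 1)], [("pFHR2_i", 1)], "k_intb_R1", "k_recb_R1")
    add(T, "R23", [("pFHR2_i", 1)], [("pFHR2_deg", 1)], "k_degb_R1")
    # --- VEGFR2 activation and trafficking (R24-R28)
    add(V, "R24", [("VEGF", 1), ("VEGFR2", 1)], [("pR2", 1)],
        "k_pR2", "k_dpR2")
    add(T, "R25", [("VEGFR2", 1)], [("VEGFR2_i", 1)], "k_intf", "k_recf")
    add(T, "R26", [("VEGFR2_i", 1)], [("VEGFR2_deg", 1)], "k_degf")
    add(T, "R27", [("pR2", 1)], [("pR2_i", 1)], "k_intb", "k_recb")
    add(T, "R28", [("pR2_i", 1)], [("pR2_deg", 1)], "k_degb")
    # --- Shc, Grb2:Sos recruitment, Ras loading (R29-R45)
    add(V, "R29", [("pR2", 1), ("Shc", 1)], [("pR2_Shc", 1)],
        "kf_shc", "kr_shc")
    add(V, "R30", [("pR2_Shc", 1)], [("pR2", 1), ("pShc", 1)], "kc_shc")
    add(V, "R31", [("pShc", 1), ("Ptase1", 1)], [("Ptase1_pShc", 1)],
        "kf_ptase1_shc", "kr_ptase1_shc")
    add(V, "R32", [("Ptase1_pShc", 1)], [("Ptase1", 1), ("Shc", 1)],
        "kc_ptase1_shc")
    add(V, "R33", [("Grb2", 1), ("Sos", 1)], [("Grb2_Sos", 1)],
        "kf_grb_sos", "kr_grb_sos")
    add(V, "R34", [("pShc", 1), ("Grb2_Sos", 1)], [("pShc_Grb2Sos", 1)],
        "kf_gs_dock", "kr_gs_dock")
    add(V, "R35", [("pShc", 1), ("Grb2", 1)], [("pShc_Grb2", 1)],
        "kf_grb_dock", "kr_grb_dock")
    add(V, "R36", [("pShc_Grb2", 1), ("Sos", 1)], [("pShc_Grb2Sos", 1)],
        "kf_grb_sos", "kr_grb_sos")
    add(V, "R37", [("pR2", 1), ("Grb2_Sos", 1)], [("pR2_Grb2Sos", 1)],
        "kf_gs_dock", "kr_gs_dock")
    add(V, "R38", [("pR2", 1), ("Grb2", 1)], [("pR2_Grb2", 1)],
        "kf_grb_dock", "kr_grb_dock")
    add(V, "R39", [("pR2_Grb2", 1), ("Sos", 1)], [("pR2_Grb2Sos", 1)],
        "kf_grb_sos", "kr_grb_sos")
    add(V, "R40", [("pShc_Grb2Sos", 1), ("Ras", 1)], [("pShcGrb2Sos_Ras", 1)],
        "kf_sos_ras", "kr_sos_ras")
    add(V, "R41", [("pShcGrb2Sos_Ras", 1)], [("pShc_Grb2Sos", 1), ("RasGTP", 1)],
        "kc_sos_ras")
    add(V, "R42", [("pR2_Grb2Sos", 1), ("Ras", 1)], [("pR2Grb2Sos_Ras", 1)],
        "kf_sos_ras", "kr_sos_ras")
    add(V, "R43", [("pR2Grb2Sos_Ras", 1)], [("pR2_Grb2Sos", 1), ("RasGTP", 1)],
        "kc_sos_ras")
    add(V, "R44", [("RasGTP", 1), ("GAP", 1)], [("GAP_RasGTP", 1)],
        "kf_gap", "kr_gap")
    add(V, "R45", [("GAP_RasGTP", 1)], [("GAP", 1), ("Ras", 1)], "kc_gap")
    # --- Raf activation/deactivation (R46-R49)
    add(V, "R46", [("RasGTP", 1), ("Raf", 1)], [("RasGTP_Raf", 1)],
        "kf_rasgtp_raf", "kr_rasgtp_raf")
    add(V, "R47", [("RasGTP_Raf", 1)], [("RasGTP", 1), ("aRaf", 1)],
        "kc_raf_act")
    add(V, "R48", [("aRaf", 1), ("Ptase1", 1)], [("Ptase1_aRaf", 1)],
        "kf_ptase1_araf", "kr_ptase1_araf")
    add(V, "R49", [("Ptase1_aRaf", 1)], [("Ptase1", 1), ("Raf", 1)],
        "kc_ptase1_araf")
    # --- MEK two-site phosphorylation by pFRS2 and aRaf (R50-R57)
    add(M, "R50", [("pFRS2", 1), ("MEK", 1)], [("pFRS2_MEK", 1)],
        "kf_pfrs2_mek", "kr_pfrs2_mek")
    add(M, "R51", [("pFRS2_MEK", 1)], [("pFRS2", 1), ("pMEK", 1)],
        "kc_pfrs2_mek")
    add(M, "R52", [("pFRS2", 1), ("pMEK", 1)], [("pFRS2_pMEK", 1)],
        "kf_pfrs2_mek", "kr_pfrs2_mek")
    add(M, "R53", [("pFRS2_pMEK", 1)], [("pFRS2", 1), ("ppMEK", 1)],
        "kc_pfrs2_mek")
    add(M, "R54", [("aRaf", 1), ("MEK", 1)], [("aRaf_MEK", 1)],
        "kf_araf_mek", "kr_araf_mek")
    add(M, "R55", [("aRaf_MEK", 1)], [("aRaf", 1), ("pMEK", 1)],
        "kc_araf_mek")
    add(M, "R56", [("aRaf", 1), ("pMEK", 1)], [("aRaf_pMEK", 1)],
        "kf_araf_mek", "kr_araf_mek")
    add(M, "R57", [("aRaf_pMEK", 1)], [("aRaf", 1), ("ppMEK", 1)],
        "kc_araf_mek")
    # --- MEK dephosphorylation by Ptase2 (R58-R61)
    add(M, "R58", [("pMEK", 1), ("Ptase2", 1)], [("Ptase2_pMEK", 1)],
        "k_dpMEK_p", "k_dpMEK_m")
    add(M, "R59", [("Ptase2_pMEK", 1)], [("Ptase2", 1), ("MEK", 1)], "ked1")
    add(M, "R60", [("ppMEK", 1), ("Ptase2", 1)], [("Ptase2_ppMEK", 1)],
        "k_dpMEK_p", "k_dpMEK_m")
    add(M, "R61", [("Ptase2_ppMEK", 1)], [("Ptase2", 1), ("pMEK", 1)], "ked2")
    # --- ERK two-site phosphorylation by ppMEK (R62-R65)
    add(M, "R62", [("ppMEK", 1), ("ERK", 1)], [("ppMEK_ERK", 1)],
        "kf_mek_erk", "kr_mek_erk")
    add(M, "R63", [("ppMEK_ERK", 1)], [("ppMEK", 1), ("pERK", 1)],
        "kc_mek_erk")
    add(M, "R64", [("ppMEK", 1), ("pERK", 1)], [("ppMEK_pERK", 1)],
        "kf_mek_erk", "kr_mek_erk")
    add(M, "R65", [("ppMEK_pERK", 1)], [("ppMEK", 1), ("ppERK", 1)],
        "kc_mek_erk")
    # --- ERK dephosphorylation by Ptase3 (R66-R69)
    add(M, "R66", [("pERK", 1), ("Ptase3", 1)], [("Ptase3_pERK", 1)],
        "kf_ptase3", "kr_ptase3")
    add(M, "R67", [("Ptase3_pERK", 1)], [("Ptase3", 1), ("ERK", 1)],
        "kc_ptase3_1")
    add(M, "R68", [("ppERK", 1), ("Ptase3", 1)], [("Ptase3_ppERK", 1)],
        "kf_ptase3", "kr_ptase3")
    add(M, "R69", [("Ptase3_ppERK", 1)], [("Ptase3", 1), ("pERK", 1)],
        "kc_ptase3_2")
    # --- intrinsic Ras-GTP hydrolysis (R70)
    add(V, "R70", [("RasGTP", 1)], [("Ras", 1)], "k_iRas")
    return rows


#: readout species subsets. pERK_total sums every free and bound singly- and
#: doubly-phosphorylated ERK form; pR2_total sums all phosphorylated VEGFR2
#: forms except the degraded pool.
READOUT_DEFS: dict[str, list[str]] = {
    "pERK_total": [
        "pERK", "ppERK", "ppMEK_pERK", "Ptase3_pERK", "Ptase3_ppERK",
        "ppERK_pFRS2", "ppERK_FRS2",
    ],
    "pR2_total": [
        "pR2", "pR2_i", "pR2_Shc", "pR2_Grb2", "pR2_Grb2Sos",
        "pR2Grb2Sos_Ras",
    ],
    "pFRS2": [
        "pFRS2", "pFRS2_MEK", "pFRS2_pMEK", "ppERK_pFRS2", "Ptase1_pFRS2",
    ],
    "ppMEK": ["ppMEK", "ppMEK_ERK", "ppMEK_pERK", "Ptase2_ppMEK"],
    "aRaf": ["aRaf", "aRaf_MEK", "aRaf_pMEK", "Ptase1_aRaf"],
    "RasGTP": ["RasGTP", "GAP_RasGTP", "RasGTP_Raf"],
    "FRS2_free": ["FRS2"],
}


def build_main_network(
    parameter_overrides: dict[str, float] | None = None,
    initial_overrides: dict[str, float] | None = None,
) -> SignalingModel:
    """Assemble the main FGF/VEGF signaling model at baseline values."""
    species = _species_table()
    if initial_overrides:
        by_name = {s.name: s for s in species}
        for name, val in initial_overrides.items():
            if name not in by_name:
                raise NetworkConfigError(f"unknown species {name!r}")
            by_name[name].initial_amount = float(val)
    rows = _reaction_table()
    params = dict(BASELINE_PARAMETERS)
    if parameter_overrides:
        unknown = set(parameter_overrides) - set(params)
        if unknown:
            raise NetworkConfigError(f"unknown parameters: {sorted(unknown)}")
        params.update(parameter_overrides)
    net = ReactionNetwork(
        species=species,
        reactions=[r for r, _ in rows],
        parameters=params,
        name="fgf_vegf_mapk_main",
    )
    net.validate()
    model = SignalingModel(
        network=net,
        arm_tags={r.label: tag for r, tag in rows},
        readout_defs={k: list(v) for k, v in READOUT_DEFS.items()},
        free_rate_constants=list(FREE_RATE_CONSTANTS),
        free_initial_amounts=list(FREE_INITIAL_AMOUNTS),
    )
    _check_counts(net, MAIN_COUNTS)
    return model


def _check_counts(net: ReactionNetwork, expected: dict[str, int]) -> None:
    got = {
        "reactions": len(net.reactions),
        "species": len(net.species),
        "parameters": len(net.parameters),
    }
    if got != expected:
        raise NetworkConfigError(f"model-integrity error: {got} != {expected}")


HEPARIN_PARAMETERS: dict[str, float] = {
    "kf_fgf_hep": 0.05,   # /nM/min, same site chemistry as surface HSGAG
    "kr_fgf_hep": 1.0,
    "kf_fhepR": 3e-4,     # FGF:heparin recruiting FGFR1 (soluble chain,
                          # less efficient than the surface-assembled route)
}


def build_heparin_extension(
    model: SignalingModel, heparin_ug_per_ml: float = 500.0
) -> SignalingModel:
    """Extend the main model with soluble-heparin competition.

    Heparin binds FGF in solution, competing with surface HSGAGs. The
    FGF:heparin complex can still recruit FGFR1 into signaling-competent
    ternary complexes (heparin is a functional HSGAG analog), but with a
    lower association rate; heparin chains carrying two FGF molecules can
    cross-link two receptors into a phosphorylated but signaling-incompetent
    assembly. The net effect on pERK is therefore dose-dependent: positive
    where free FGF is in excess of surface capacity and negative where
    heparin simply sequesters scarce FGF.
    """
    if heparin_ug_per_ml < 0:
        raise ValueError("heparin dose must be non-negative")
    hep_nM = ligand_unit_convert(heparin_ug_per_ml * 1000.0, "ng_per_ml", "heparin")

    E, S, I, D = "extracellular", "surface", "internal", "degraded_pool"
    new_species = [
        Species("Hep", E, hep_nM, clamped=True),
        Species("FGF_Hep", E, 0.0, clamped=True),
        Species("FHepR", S), Species("FHepR2", S), Species("pFHepR2", S),
        Species("pFHepR2_FRS2", S),
        Species("FHRmix", S), Species("pFHRmix", S),
        Species("pFHRmix_FRS2", S),
        Species("FHepR_i", I), Species("FHepR_deg", D),
        Species("FHepR2_i", I), Species("FHepR2_deg", D),
        Species("pFHepR2_i", I), Species("pFHepR2_deg", D),
        Species("FHRmix_i", I), Species("FHRmix_deg", D),
        Species("pFHRmix_i", I), Species("pFHRmix_deg", D),
        Species("FGF2_Hep", E, 0.0, clamped=True),
        Species("F2HepR", S),
        Species("F2HepR_i", I), Species("F2HepR_deg", D),
        Species("F2HepR2", S), Species("pF2HepR2", S),
    ]
    R = Reaction
    new_reactions = [
        # heparin capturing FGF in solution (two equivalent sites per chain)
        R("E1", [("FGF", 1), ("Hep", 1)], [("FGF_Hep", 1)],
          "kf_fgf_hep", "kr_fgf_hep"),
        R("E21", [("FGF_Hep", 1), ("FGF", 1)], [("FGF2_Hep", 1)],
          "kf_fgf_hep", "kr_fgf_hep"),
        # receptor recruitment by heparin-held FGF
        R("E2", [("FGF_Hep", 1), ("FGFR1", 1)], [("FHepR", 1)],
          "kf_fhepR", "kr_fhr"),
        R("E22", [("FGF2_Hep", 1), ("FGFR1", 1)], [("F2HepR", 1)],
          "kf_fhepR", "kr_fhr"),
        R("E25", [("F2HepR", 1), ("FGFR1", 1)], [("F2HepR2", 1)],
          "kf_fhepR", "kr_fhr"),
        # dimerization (pure heparin dimer, and mixed with the HSGAG ternary)
        R("E3", [("FHepR", 2)], [("FHepR2", 1)], "kf_dim", "kr_dim"),
        R("E4", [("FHepR", 1), ("FHR", 1)], [("FHRmix", 1)],
          "kf_dim", "kr_dim"),
        # activation
        R("E5", [("FHepR2", 1)], [("pFHepR2", 1)], "k_pR1", "k_dpR1"),
        R("E6", [("FHRmix", 1)], [("pFHRmix", 1)], "k_pR1", "k_dpR1"),
        R("E26", [("F2HepR2", 1)], [("pF2HepR2", 1)], "k_pR1", "k_dpR1"),
        # FRS2 phosphorylation by the active heparin-containing dimers
        R("E7", [("pFHepR2", 1), ("FRS2", 1)], [("pFHepR2_FRS2", 1)],
          "kf_frs2_bind", "kr_frs2_bind"),
        R("E8", [("pFHepR2_FRS2", 1)], [("pFHepR2", 1), ("pFRS2", 1)],
          "kc_frs2_phos"),
        R("E9", [("pFHRmix", 1), ("FRS2", 1)], [("pFHRmix_FRS2", 1)],
          "kf_frs2_bind", "kr_frs2_bind"),
        R("E10", [("pFHRmix_FRS2", 1)], [("pFHRmix", 1), ("pFRS2", 1)],
          "kc_frs2_phos"),
        # trafficking of the new bound forms (shared FGFR1 bound-rate set)
        R("E11", [("FHepR", 1)], [("FHepR_i", 1)], "k_intb_R1", "k_recb_R1"),
        R("E12", [("FHepR_i", 1)], [("FHepR_deg", 1)], "k_degb_R1"),
        R("E13", [("FHepR2", 1)], [("FHepR2_i", 1)], "k_intb_R1", "k_recb_R1"),
        R("E14", [("FHepR2_i", 1)], [("FHepR2_deg", 1)], "k_degb_R1"),
        R("E15", [("pFHepR2", 1)], [("pFHepR2_i", 1)],
          "k_intb_R1", "k_recb_R1"),
        R("E16", [("pFHepR2_i", 1)], [("pFHepR2_deg", 1)], "k_degb_R1"),
        R("E17", [("FHRmix", 1)], [("FHRmix_i", 1)], "k_intb_R1", "k_recb_R1"),
        R("E18", [("FHRmix_i", 1)], [("FHRmix_deg", 1)], "k_degb_R1"),
        R("E19", [("pFHRmix", 1)], [("pFHRmix_i", 1)],
          "k_intb_R1", "k_recb_R1"),
        R("E20", [("pFHRmix_i", 1)], [("pFHRmix_deg", 1)], "k_degb_R1"),
        R("E23", [("F2HepR", 1)], [("F2HepR_i", 1)], "k_intb_R1", "k_recb_R1"),
        R("E24", [("F2HepR_i", 1)], [("F2HepR_deg", 1)], "k_degb_R1"),
    ]
    base = model.network
    net = ReactionNetwork(
        species=[Species(s.name, s.compartment, s.initial_amount, s.clamped)
                 for s in base.species] + new_species,
        reactions=list(base.reactions) + new_reactions,
        parameters={**base.parameters, **HEPARIN_PARAMETERS},
        name="fgf_vegf_mapk_heparin",
    )
    net.validate()
    _check_counts(net, {k: MAIN_COUNTS[k] + HEPARIN_EXTRA[k]
                        for k in MAIN_COUNTS})
    ext = SignalingModel(
        network=net,
        arm_tags={**model.arm_tags,
                  **{r.label: "heparin" for r in new_reactions}},
        readout_defs={k: list(v) for k, v in model.readout_defs.items()},
        free_rate_constants=list(model.free_rate_constants),
        free_initial_amounts=list(model.free_initial_amounts),
    )
    return ext


def heparin_partition(
    fgf_tot_nM: float, hep_chains_nM: float, k_site_per_nM: float
) -> tuple[float, float, float]:
    """Equilibrium partition of the FGF dose over soluble heparin chains.

    Heparin chains carry two equivalent, independent FGF sites with
    association constant ``k_site_per_nM`` (kf_fgf_hep/kr_fgf_hep). The
    extracellular reservoir is large and the window short, so the solution
    pools are held at this equilibrium (clamped) during integration.

    Returns (free FGF, singly loaded chains, doubly loaded chains) in nM.
    """
    if fgf_tot_nM < 0 or hep_chains_nM < 0:
        raise ValueError("doses must be non-negative")
    if fgf_tot_nM == 0 or hep_chains_nM == 0 or k_site_per_nM == 0:
        return fgf_tot_nM, 0.0, 0.0
    from scipy.optimize import brentq

    K = k_site_per_nM
    H = hep_chains_nM

    def residual(f_free):
        p = K * f_free / (1.0 + K * f_free)  # per-site occupancy
        return f_free + H * (2 * p * (1 - p) + 2 * p * p) - fgf_tot_nM

    f_free = brentq(residual, 0.0, fgf_tot_nM, xtol=1e-15, rtol=1e-12)
    p = K * f_free / (1.0 + K * f_free)
    return f_free, H * 2 * p * (1 - p), H * p * p
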