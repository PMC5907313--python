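"""Packaged reference network and the analytic toy-branch oracle.

The reference network is a reduced, calibrated surrogate of a whole-body
liver-metabolism model: six compartments (liver, blood, adipose, pancreas,
macrophage, other tissue), the twenty named branch reactions of the published
catalog (k159 MAG -> glycerol, k152 acetoacetate -> beta-hydroxybutyrate,
k177 hepatic TG -> adipose lipid droplet, ...), thirteen regulatory factors,
three inversely sex-regulated marker genes, the three diet sources and the
full hormonal layer.  Scaffolding species/reactions (ids prefixed ``s_`` or
``r_``) connect the catalog reactions into a normalizable flux network.

Branch fractions and regulatory weights are free calibration parameters of
the surrogate: they were fixed once (see ``scripts/build_reference.py``) so
that the network reproduces the qualitative sensitivity structure of the
full-scale model - which reactions dominate hepatic triglyceride
accumulation, which cross the high-sensitivity threshold per sex, which
regulators respond at the k159 branch, and the inverse sex-dependent marker
responses - not its absolute coefficient magnitudes.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

from .document import (
    BranchPoint,
    FluxSource,
    HormoneProfile,
    ModelDocument,
    Reaction,
    ReceptorPair,
    RegulatoryEdge,
    Species,
)
from .hormones import configure_sex

__all__ = [
    "CATALOG_REACTIONS",
    "REGULATORS",
    "MARKER_GENES",
    "build_reference_document",
    "load_reference",
    "reference_digest",
    "generate_toy_branch_network",
]

#: the twenty named branch reactions of the catalog and their readings
CATALOG_REACTIONS = {
    "k159": "MAG -> Glycerol",
    "k152": "Acetoacetate -> beta-hydroxybutyrate",
    "k177": "TG -> adipose TG lipid droplet",
    "k180": "Chylomicron -> Chylomicron remnants",
    "k500": "TG -> VLDL",
    "k1051": "Blood glucose -> Adipose glucose",
    "k179": "Blood fatty acids -> tissue fatty acids",
    "k154": "Blood beta-hydroxybutyrate -> adipose beta-hydroxybutyrate",
    "k155": "Blood acetoacetate -> adipose acetoacetate",
    "k169": "Adipose fatty acids -> unsaturated FattyAcylCoA",
    "k170": "Adipose fatty acids -> saturated FattyAcylCoA",
    "k166": "Blood cholesterol -> tissue cholesterol",
    "k165": "Blood cholesterol -> adipose cholesterol",
    "k164": "Blood cholesterol -> macrophage cholesterol",
    "k150": "Acetoacetate -> blood acetoacetate",
    "k142": "Fructose-1,6BP -> DHAP",
    "k173": "DAG -> TG",
    "k187": "Oxoglutarate + Ammonia -> Glutamate",
    "k172": "FattyAcylCoA + Glycerol3P -> LPA",
    "k1071": "Hepatic glucose -> blood glucose",
}

#: branch ids without a published reading; carried as scaffolding branches
UNMAPPED_IDS = ("k163", "k144", "k800", "k102", "k105", "k176")

REGULATORS = (
    "PGC1A",
    "PPARa",
    "FXR",
    "LXR",
    "ChREBP",
    "SREBP1c",
    "SREBP2",
    "Adiponectin",
    "TNFa",
    "Glucagon",
    "Glucocorticoid",
    "Cholesterol",
    "Glucose",
)

MARKER_GENES = ("Agpat", "Prkaa", "Irs")

#: the hepatic triglyceride storage pool observed by the sensitivity analysis
TG_OUTPUT_SPECIES = "TG_hepatic_droplet"

# -- calibrated sex-dependent weights (see module docstring) ---------------
_MALE_EDGES = [
    # sex-modulated lipogenic activation of hepatic droplet storage
    dict(id="e_glycerol_lipogenesis", regulator="Glycerol", target="k176", sign=1, weight=2.2),
    dict(id="e_ketone_lipogenesis", regulator="BHB_liver", target="k176", sign=1, weight=0.05),
    # inverse sex-dependent marker-gene regulation by hepatic lipid load
    dict(id="e_lipid_Agpat", regulator="TG_liver", target="syn_Agpat", sign=-1, weight=0.30),
    dict(id="e_lipid_Prkaa", regulator="TG_liver", target="syn_Prkaa", sign=-1, weight=0.25),
    dict(id="e_lipid_Irs", regulator="TG_liver", target="syn_Irs", sign=1, weight=0.25),
    # active-receptor links into the liver
    dict(id="e_ghr_vldl", regulator="GHR_active", target="k500", sign=1, weight=0.1),
    dict(id="e_ar_oxidation", regulator="AR_active", target="r_beta_oxidation", sign=1, weight=0.1),
    dict(id="e_er_lipid_uptake", regulator="ER_active", target="r_remnant_uptake", sign=1, weight=0.1),
]

_FEMALE_EDGES = [
    dict(id="e_glycerol_lipogenesis", regulator="Glycerol", target="k176", sign=1, weight=4.4),
    dict(id="e_ketone_lipogenesis", regulator="BHB_liver", target="k176", sign=1, weight=1.65),
    dict(id="e_lipid_Agpat", regulator="TG_liver", target="syn_Agpat", sign=1, weight=0.30),
    dict(id="e_lipid_Prkaa", regulator="TG_liver", target="syn_Prkaa", sign=1, weight=0.25),
    dict(id="e_lipid_Irs", regulator="TG_liver", target="syn_Irs", sign=-1, weight=0.25),
    dict(id="e_ghr_vldl", regulator="GHR_active", target="k500", sign=1, weight=0.1),
    dict(id="e_ar_oxidation", regulator="AR_active", target="r_beta_oxidation", sign=1, weight=0.1),
    dict(id="e_er_lipid_uptake", regulator="ER_active", target="r_remnant_uptake", sign=1, weight=0.1),
]


def build_reference_document() -> ModelDocument:
    """Deterministically construct the base (unconfigured) reference network."""
    sp = []
    rx = []
    br = []
    ed = []
    fs = []
    pairs = []

    def S(id, compartment, role="metabolite", name="", boundary=False):
        sp.append(Species(id=id, name=name or id, compartment=compartment,
                          role=role, is_boundary=boundary))

    def R(id, subs, prods, name=""):
        rx.append(Reaction(id=id, substrates=subs, products=prods))

    def B(id, source, fractions):
        br.append(BranchPoint(id=id, source_species=source, fractions=fractions))

    def E(id, regulator, target, sign, weight):
        ed.append(RegulatoryEdge(id=id, regulator=regulator, target=target,
                                 sign=sign, weight=weight))

    def F(id, target, basal):
        fs.append(FluxSource(id=id, target_species=target, basal_rate=basal))

    # ---- hormonal layer ------------------------------------------------
    for h in ("growth_hormone", "androgen", "estrogen"):
        S(h, "blood", role="hormone")
        F(f"{h}_source", h, 1.0)
        R(f"r_{h}_clearance", [(h, 1)], [])
    for h, rec in (("growth_hormone", "GHR"), ("androgen", "AR"), ("estrogen", "ER")):
        S(f"{rec}_inactive", "liver", role="receptor_inactive")
        S(f"{rec}_active", "liver", role="receptor_active")
        pairs.append(ReceptorPair(hormone=h, inactive_species=f"{rec}_inactive",
                                  active_species=f"{rec}_active",
                                  half_saturation=1.0, total=1.0))

    # ---- dietary lipid / hepatic triglyceride core ---------------------
    S("Chylomicron", "blood")
    S("ChylomicronRemnant", "blood")
    S("TG_liver", "liver")
    S("TG_hepatic_droplet", "liver", name="hepatic TG lipid droplet")
    S("VLDL", "blood")
    S("TG_adipose_droplet", "adipose", name="adipose TG lipid droplet")
    S("DAG", "liver")
    S("MAG", "liver")
    S("Glycerol", "liver")
    S("Glycerol3P", "liver")
    S("LPA", "liver")
    F("triglyceride", "Chylomicron", 1.0)
    F("mag_influx", "MAG", 0.5)
    R("k180", [("Chylomicron", 1)], [("ChylomicronRemnant", 1)])
    R("k163", [("Chylomicron", 1)], [("FA_adipose", 1)])
    B("B_chylomicron", "Chylomicron", {"k180": 0.5, "k163": 0.5})
    R("r_remnant_uptake", [("ChylomicronRemnant", 1)], [("TG_liver", 1)])
    R("k177", [("TG_liver", 1)], [("TG_adipose_droplet", 1)])
    R("k500", [("TG_liver", 1)], [("VLDL", 1)])
    R("k176", [("TG_liver", 1)], [("TG_hepatic_droplet", 1)])
    B("B_tg_liver", "TG_liver", {"k177": 0.60, "k500": 0.25, "k176": 0.15})
    R("r_droplet_turnover", [("TG_hepatic_droplet", 1)], [])
    R("r_vldl_clearance", [("VLDL", 1)], [])
    R("r_adipose_droplet_turnover", [("TG_adipose_droplet", 1)], [])
    R("k173", [("DAG", 1)], [("TG_liver", 1)])
    R("s_dag_to_mag", [("DAG", 1)], [("MAG", 1)])
    B("B_dag", "DAG", {"k173": 0.6, "s_dag_to_mag": 0.4})
    R("k159", [("MAG", 1)], [("Glycerol", 1)])
    R("s_mag_to_fa", [("MAG", 1)], [("FA_liver", 1)])
    R("s_mag_to_dag", [("MAG", 1)], [("DAG", 1)])
    R("s_mag_secretion", [("MAG", 1)], [])
    R("s_mag_phospholipid", [("MAG", 1)], [])
    B("B_mag", "MAG", {"k159": 0.24, "s_mag_to_fa": 0.20, "s_mag_to_dag": 0.19,
                       "s_mag_secretion": 0.19, "s_mag_phospholipid": 0.18})
    R("r_glycerol_kinase", [("Glycerol", 1)], [("Glycerol3P", 1)])
    R("k172", [("Glycerol3P", 1), ("FACoA_liver", 1)], [("LPA", 1)])
    R("s_g3p_to_dhap", [("Glycerol3P", 1)], [("DHAP", 1)])
    B("B_glycerol3p", "Glycerol3P", {"k172": 0.3, "s_g3p_to_dhap": 0.7})
    R("r_lpa_to_dag", [("LPA", 1)], [("DAG", 1)])

    # droplet storage regulation (weights are sex-configured)
    E("e_glycerol_lipogenesis", "Glycerol", "k176", 1, 2.2)
    E("e_ketone_lipogenesis", "BHB_liver", "k176", 1, 0.05)
    E("e_droplet_feedback", "TG_hepatic_droplet", "k176", -1, 0.05)

    # ---- fatty acids ---------------------------------------------------
    S("FA_blood", "blood")
    S("FA_liver", "liver")
    S("FA_tissue", "other_tissue")
    S("FA_adipose", "adipose")
    S("FACoA_liver", "liver")
    S("FACoA_unsat_adipose", "adipose", name="unsaturated FattyAcylCoA")
    S("FACoA_sat_adipose", "adipose", name="saturated FattyAcylCoA")
    F("fa_influx", "FA_blood", 0.7)
    R("k179", [("FA_blood", 1)], [("FA_tissue", 1)])
    R("s_fab_to_liver", [("FA_blood", 1)], [("FA_liver", 1)])
    R("s_fab_to_adipose", [("FA_blood", 1)], [("FA_adipose", 1)])
    B("B_fa_blood", "FA_blood", {"k179": 0.35, "s_fab_to_liver": 0.35,
                                 "s_fab_to_adipose": 0.30})
    R("r_fa_tissue_use", [("FA_tissue", 1)], [])
    R("r_fa_activation", [("FA_liver", 1)], [("FACoA_liver", 1)])
    R("r_beta_oxidation", [("FACoA_liver", 1)], [("AcAc_liver", 1)])
    R("k169", [("FA_adipose", 1)], [("FACoA_unsat_adipose", 1)])
    R("k170", [("FA_adipose", 1)], [("FACoA_sat_adipose", 1)])
    B("B_fa_adipose", "FA_adipose", {"k169": 0.5, "k170": 0.5})
    R("r_esterification_unsat", [("FACoA_unsat_adipose", 1)], [("TG_adipose_droplet", 1)])
    R("r_esterification_sat", [("FACoA_sat_adipose", 1)], [("TG_adipose_droplet", 1)])

    # ---- ketone bodies -------------------------------------------------
    S("AcAc_liver", "liver", name="acetoacetate (liver)")
    S("BHB_liver", "liver", name="beta-hydroxybutyrate (liver)")
    S("AcAc_blood", "blood")
    S("BHB_blood", "blood")
    S("AcAc_adipose", "adipose")
    S("BHB_adipose", "adipose")
    S("AcAc_tissue", "other_tissue")
    S("BHB_tissue", "other_tissue")
    F("ketogenic_influx", "AcAc_liver", 0.45)
    R("k152", [("AcAc_liver", 1)], [("BHB_liver", 1)])
    R("k150", [("AcAc_liver", 1)], [("AcAc_blood", 1)])
    R("s_acac_decarboxylation", [("AcAc_liver", 1)], [])
    B("B_acac_liver", "AcAc_liver", {"k152": 0.4, "k150": 0.3,
                                     "s_acac_decarboxylation": 0.3})
    R("r_bhb_export", [("BHB_liver", 1)], [("BHB_blood", 1)])
    R("k154", [("BHB_blood", 1)], [("BHB_adipose", 1)])
    R("s_bhbb_to_tissue", [("BHB_blood", 1)], [("BHB_tissue", 1)])
    B("B_bhb_blood", "BHB_blood", {"k154": 0.5, "s_bhbb_to_tissue": 0.5})
    R("k155", [("AcAc_blood", 1)], [("AcAc_adipose", 1)])
    R("s_acacb_to_tissue", [("AcAc_blood", 1)], [("AcAc_tissue", 1)])
    B("B_acac_blood", "AcAc_blood", {"k155": 0.5, "s_acacb_to_tissue": 0.5})
    for sid in ("BHB_adipose", "BHB_tissue", "AcAc_adipose", "AcAc_tissue"):
        R(f"r_{sid.lower()}_use", [(sid, 1)], [])

    # ---- glucose axis --------------------------------------------------
    S("Glucose_blood", "blood")
    S("Glucose_liver", "liver")
    S("Glucose_adipose", "adipose")
    S("Glucose_tissue", "other_tissue")
    S("DHAP", "liver")
    S("F16BP", "liver", name="fructose-1,6-bisphosphate")
    F("glucose", "Glucose_blood", 1.0)
    R("k1051", [("Glucose_blood", 1)], [("Glucose_adipose", 1)])
    R("k800", [("Glucose_blood", 1)], [("Glucose_tissue", 1)])
    B("B_glucose_blood", "Glucose_blood", {"k1051": 0.3, "k800": 0.7})
    R("r_glc_adipose_use", [("Glucose_adipose", 1)], [])
    R("r_glc_tissue_use", [("Glucose_tissue", 1)], [])
    R("r_gluconeogenesis", [("DHAP", 1)], [("Glucose_liver", 1)])
    R("k1071", [("Glucose_liver", 1)], [("Glucose_blood", 1)])
    R("k102", [("Glucose_liver", 1)], [("F16BP", 1)])
    B("B_glucose_liver", "Glucose_liver", {"k1071": 0.6, "k102": 0.4})
    R("k142", [("F16BP", 1)], [("DHAP", 1)])
    R("k144", [("F16BP", 1)], [])
    B("B_f16bp", "F16BP", {"k142": 0.5, "k144": 0.5})

    # ---- cholesterol ---------------------------------------------------
    S("Chol_liver", "liver")
    S("Chol_blood", "blood")
    S("Chol_tissue", "other_tissue")
    S("Chol_adipose", "adipose")
    S("Chol_macrophage", "macrophage")
    F("cholesterol", "Chol_blood", 1.0)
    F("chol_synthesis", "Chol_liver", 0.3)
    E("e_glucose_chol_synthesis", "Glucose_liver", "chol_synthesis", 1, 0.9)
    R("r_chol_export", [("Chol_liver", 1)], [("Chol_blood", 1)])
    third = 1.0 / 3.0
    R("k166", [("Chol_blood", 1)], [("Chol_tissue", 1)])
    R("k165", [("Chol_blood", 1)], [("Chol_adipose", 1)])
    R("k164", [("Chol_blood", 1)], [("Chol_macrophage", 1)])
    B("B_chol_blood", "Chol_blood", {"k166": third, "k165": third,
                                     "k164": 1.0 - 2 * third})
    for sid in ("Chol_tissue", "Chol_adipose", "Chol_macrophage"):
        R(f"r_{sid.lower()}_use", [(sid, 1)], [])

    # ---- amino-acid node -----------------------------------------------
    S("Oxoglutarate", "liver")
    S("Ammonia", "liver")
    S("Glutamate", "liver")
    F("og_influx", "Oxoglutarate", 0.4)
    F("ammonia_influx", "Ammonia", 0.2)
    R("k187", [("Oxoglutarate", 1), ("Ammonia", 1)], [("Glutamate", 1)])
    R("k105", [("Oxoglutarate", 1)], [])
    B("B_oxoglutarate", "Oxoglutarate", {"k187": 0.5, "k105": 0.5})
    R("r_glutamate_use", [("Glutamate", 1)], [])

    # ---- pancreatic insulin --------------------------------------------
    S("Insulin", "pancreas", role="protein")
    F("insulin_secretion", "Insulin", 0.25)
    E("e_glucose_insulin", "Glucose_blood", "insulin_secretion", 1, 0.8)
    R("r_insulin_clearance", [("Insulin", 1)], [])
    E("e_insulin_uptake", "Insulin", "r_glc_adipose_use", 1, 0.3)

    # ---- regulatory factors --------------------------------------------
    for rid in REGULATORS:
        S(rid, "liver", role="regulator")
        F(f"syn_{rid}", rid, 0.25)
        R(f"r_deg_{rid}", [(rid, 1)], [])
    sensing = [
        ("e_glucose_glucagon", "Glucose_liver", "syn_Glucagon", -1, 0.95),
        ("e_glucose_sensor", "Glucose_liver", "syn_Glucose", 1, 1.1),
        ("e_glucose_chrebp", "Glucose_liver", "syn_ChREBP", 1, 0.8),
        ("e_chol_sensor", "Chol_liver", "syn_Cholesterol", 1, 0.85),
        ("e_chol_srebp2", "Chol_liver", "syn_SREBP2", -1, 0.8),
        ("e_chol_lxr", "Chol_blood", "syn_LXR", 1, 0.45),
        ("e_glcb_srebp1c", "Glucose_blood", "syn_SREBP1c", 1, 0.5),
        ("e_bhb_pgc1a", "BHB_liver", "syn_PGC1A", 1, 0.3),
        ("e_adipose_adiponectin", "TG_adipose_droplet", "syn_Adiponectin", -1, 0.35),
        ("e_fa_ppara", "FA_liver", "syn_PPARa", 1, 0.4),
        ("e_fa_fxr", "FA_liver", "syn_FXR", 1, 0.3),
        ("e_chol_tnfa", "Chol_macrophage", "syn_TNFa", 1, 0.4),
        ("e_glcb_glucocorticoid", "Glucose_blood", "syn_Glucocorticoid", -1, 0.4),
    ]
    for args in sensing:
        E(*args)

    # ---- marker genes (edges installed per sex) ------------------------
    for gid in MARKER_GENES:
        S(gid, "liver", role="mrna")
        F(f"syn_{gid}", gid, 0.2)
        R(f"r_deg_{gid}", [(gid, 1)], [])
    for item in _MALE_EDGES:
        if item["id"].startswith("e_lipid_") or item["id"] in (
            "e_glycerol_lipogenesis", "e_ketone_lipogenesis",
        ):
            existing = {e.id for e in ed}
            if item["id"] not in existing:
                E(item["id"], item["regulator"], item["target"],
                  item["sign"], item["weight"])
        else:
            E(item["id"], item["regulator"], item["target"],
              item["sign"], item["weight"])

    doc = ModelDocument(
        species=sp,
        reactions=rx,
        branch_points=br,
        regulatory_edges=ed,
        flux_sources=fs,
        hormone_profiles=[
            HormoneProfile("growth_hormone", "constant", 1.0),
            HormoneProfile("androgen", "constant", 1.0),
            HormoneProfile("estrogen", "constant", 1.0),
        ],
        receptor_pairs=pairs,
        metadata={
            "name": "reference_network",
            "description": (
                "Reduced calibrated surrogate of a sex-dimorphic multi-tissue "
                "liver metabolism network"
            ),
            "catalog": dict(CATALOG_REACTIONS),
            "unmapped_ids": list(UNMAPPED_IDS),
            "tg_output_species": TG_OUTPUT_SPECIES,
            "sex_configurations": {
                "male": {"edges": _MALE_EDGES},
                "female": {"edges": _FEMALE_EDGES},
            },
        },
    )
    doc.validate()
    return doc


def _asset_text():
    return resources.files("liversim").joinpath("data/reference_network.json").read_text()


def load_reference(sex=None) -> ModelDocument:
    """Load the packaged reference network, optionally configured for a sex."""
    doc = ModelDocument.from_dict(json.loads(_asset_text()))
    doc.validate()
    if sex is not None:
        doc = configure_sex(doc, sex)
    return doc


def reference_digest() -> str:
    """SHA-256 of the packaged reference asset (regression lock)."""
    return hashlib.sha256(_asset_text().encode()).hexdigest()


def generate_toy_branch_network(fractions, chain_depth: int = 2, seed=None):
    """Hub-and-chains oracle network with closed-form control coefficients.

    A unit source feeds a hub species whose outflow splits into
    ``len(fractions)`` linear chains of ``chain_depth`` species ending in a
    boundary sink.  Under proportional sibling rescale the concentration
    control coefficient of chain j's terminal species with respect to branch
    fraction i is exactly +1 for i == j and -f_i / (1 - f_i) otherwise, at
    every increment - the analytic table returned alongside the document.

    When ``fractions`` is None, a random simplex point is drawn from ``seed``.
    """
    import numpy as np

    if fractions is None:
        rng = np.random.default_rng(seed)
        raw = rng.dirichlet(np.full(3, 5.0))
        fractions = [float(f) for f in raw]
        fractions[-1] = 1.0 - sum(fractions[:-1])
    fractions = [float(f) for f in fractions]
    n = len(fractions)
    if not (2 <= n <= 5):
        raise ValueError("need between 2 and 5 branch fractions")
    if any(not (0.0 < f < 1.0) for f in fractions):
        raise ValueError("every fraction must lie in (0, 1)")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if chain_depth < 1:
        raise ValueError("chain_depth must be >= 1")

    species = [Species(id="hub", compartment="liver")]
    reactions = []
    branch_fracs = {}
    terminals = {}
    species.append(Species(id="sink", compartment="blood", is_boundary=True))
    for i, f in enumerate(fractions):
        prev = None
        for d in range(chain_depth):
            sid = f"chain{i}_s{d + 1}"
            species.append(Species(id=sid, compartment="liver"))
            if d == 0:
                bid = f"b{i}"
                reactions.append(Reaction(id=bid, substrates=[("hub", 1)],
                                          products=[(sid, 1)]))
                branch_fracs[bid] = f
            else:
                reactions.append(Reaction(id=f"c{i}_{d}",
                                          substrates=[(prev, 1)],
                                          products=[(sid, 1)]))
            prev = sid
        reactions.append(Reaction(id=f"t{i}", substrates=[(prev, 1)],
                                  products=[("sink", 1)]))
        terminals[f"b{i}"] = prev

    doc = ModelDocument(
        species=species,
        reactions=reactions,
        branch_points=[BranchPoint(id="B_hub", source_species="hub",
                                   fractions=branch_fracs)],
        flux_sources=[FluxSource(id="feed", target_species="hub", basal_rate=1.0)],
        metadata={"name": "toy_branch_network", "terminals": dict(terminals)},
    )
    doc.validate()

    analytic = {}
    for i, fi in enumerate(fractions):
        for j in range(n):
            coeff = 1.0 if i == j else -fi / (1.0 - fi)
            analytic[(f"b{i}", terminals[f"b{j}"])] = coeff
    return doc, analytic
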