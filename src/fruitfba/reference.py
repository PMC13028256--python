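"""Reduced reference model of ripening peach mesocarp and scenario contrasts.

The full curated fruit network (185 reactions) is not reproducible from
published text, so this module ships a reduced, fully connected stand-in
(~65 reactions over the same nine metabolic processes) in which the eight
experimentally highlighted reactions appear with their reported
stoichiometries and the pipeline's qualitative behaviour is exact:

* chlorogenate is reachable only through HQT followed by 3'-hydroxylation;
* dehydroquinate comes only from vacuolar quinate via QDH run in reverse
  (no erythrose-4-P/DAHP entry into the shikimate pathway), one unit per
  aromatic ring made — one for the chlorogenate acyl moiety, one for
  cyanidin — so QDH carries flux −2 per unit RQS;
* ethylene synthesis (lumped Yang cycle) co-produces HCN, detoxified only
  by β-cyanoalanine synthase (CAS);
* the two phenylpropanoid hydroxylases each oxidize 2 GSH → GSSG,
  re-reduced only by glutathione reductase (GR);
* cytosolic NADH is re-oxidized by a non-phosphorylating external
  dehydrogenase, so the maintenance + biosynthesis ATP demand exceeds
  substrate-level capacity and forces a complete TCA turn (ACO, FUM) plus
  lumped oxidative phosphorylation;
* galacturonate derives from a mobilizable pectin reserve.

Scenario contrasts emulate the four variety × transition comparisons
(MG/RP × E1vsE2/E3vsE4) with class-conditional log2 fold-change draws.
"""

from __future__ import annotations

import math
from typing import Dict, List, Set, Tuple

import numpy as np

from .expression import ExpressionContrast, GeneClass
from .io import parse_gpr, parse_reaction_table
from .model import MetabolicModel

__all__ = [
    "CONTRAST_IDS",
    "HQT_GENE",
    "QDH_GENE",
    "TABLE_REACTIONS",
    "build_reference_model",
    "reference_model_table",
    "relative_growth_rate",
    "scenario_contrast",
    "scenario_gene_classes",
]

#: Published gene ids for the two focal enzymes; all other genes are synthetic.
HQT_GENE = "Prupe.3G101000"
QDH_GENE = "Prupe.6G166100"

#: The eight experimentally highlighted reactions, reported stoichiometries.
TABLE_REACTIONS = {
    "ACO_m": "cit_m <=> isocit_m",
    "CAS_c": "cys_c + hcn_c --> cyanoala_c + h2s_c + h_c",
    "EPSPS_c": "pep_c + s3p_c --> epsp_c + pi_c",
    "FUM_m": "fum_m + h2o_m <=> mal_m",
    "GR_c": "gssg_c + h_c + nadph_c --> 2.0 gsh_c + nadp_c",
    "HQT_c": "pcoumcoa_c + quinate_c <=> coa_c + pcoumaroylqnt_c",
    "PPA_AT_c": "glu_c + prephenate_c --> akg_c + arogenate_c",
    "QDH_c": "dhq_c + h_c + nadh_c <=> nad_c + quinate_c",
}

# (id, equation, has_gene, subsystem); lumped steps noted in equations.
_REACTION_ROWS: List[Tuple[str, str, bool, str]] = [
    # -- central carbon -------------------------------------------------
    ("GLYC_c", "glc_c + 2.0 pi_c + 2.0 nad_c --> 2.0 pep_c + 2.0 nadh_c + 2.0 h2o_c",
     True, "Central carbon/glycolysis"),
    ("PK_c", "pep_c + adp_c + h_c --> pyr_c + atp_c",
     True, "Central carbon/glycolysis"),
    ("OPP_c", "glc_c + 12.0 nadp_c + 6.0 h2o_c --> 12.0 nadph_c + 6.0 co2_c + 12.0 h_c",
     True, "Central carbon/glycolysis"),
    ("ACS_c",
     "pyr_c + coa_c + atp_c + nad_c + h2o_c --> "
     "accoa_c + co2_c + adp_c + pi_c + nadh_c + h_c",
     True, "Central carbon/glycolysis"),
    # -- TCA cycle ------------------------------------------------------
    ("PDH_m", "pyr_m + coa_m + nad_m --> accoa_m + co2_m + nadh_m", True, "TCA cycle"),
    ("CS_m", "accoa_m + oaa_m + h2o_m --> cit_m + coa_m + h_m", True, "TCA cycle"),
    ("ACO_m", TABLE_REACTIONS["ACO_m"], True, "TCA cycle"),
    ("IDH_m", "isocit_m + nad_m --> akg_m + co2_m + nadh_m", True, "TCA cycle"),
    ("AKGDH_m", "akg_m + nad_m + adp_m + pi_m --> succ_m + co2_m + nadh_m + atp_m",
     True, "TCA cycle"),
    ("SDH_m", "succ_m + nad_m --> fum_m + nadh_m", True, "TCA cycle"),
    ("FUM_m", TABLE_REACTIONS["FUM_m"], True, "TCA cycle"),
    ("MDH_m", "mal_m + nad_m <=> oaa_m + nadh_m + h_m", True, "TCA cycle"),
    # -- oxidative phosphorylation (lumped) -----------------------------
    ("OXPHOS_m",
     "2.0 nadh_m + o2_m + 5.0 adp_m + 5.0 pi_m + 2.0 h_m --> "
     "2.0 nad_m + 5.0 atp_m + 7.0 h2o_m",
     True, "Oxidative phosphorylation"),
    ("NDEX_m", "2.0 nadh_c + o2_c + 2.0 h_c --> 2.0 nad_c + 2.0 h2o_c",
     True, "Oxidative phosphorylation"),
    # -- shikimate pathway ----------------------------------------------
    ("QDH_c", TABLE_REACTIONS["QDH_c"], True, "Shikimate pathway"),
    ("DHQD_c", "dhq_c --> dhshik_c + h2o_c", True, "Shikimate pathway"),
    ("SDHR_c", "dhshik_c + nadph_c + h_c --> shik_c + nadp_c", True, "Shikimate pathway"),
    ("SK_c", "shik_c + atp_c --> s3p_c + adp_c + h_c", True, "Shikimate pathway"),
    ("EPSPS_c", TABLE_REACTIONS["EPSPS_c"], True, "Shikimate pathway"),
    ("CHRS_c", "epsp_c --> chorismate_c + pi_c", True, "Shikimate pathway"),
    ("CHRM_c", "chorismate_c --> prephenate_c", True, "Shikimate pathway"),
    ("PPA_AT_c", TABLE_REACTIONS["PPA_AT_c"], True, "Shikimate pathway"),
    ("ADT_c", "arogenate_c --> phe_c + h2o_c + co2_c", True, "Shikimate pathway"),
    # -- phenylpropanoid / chlorogenate ---------------------------------
    ("PAL_c", "phe_c --> cinm_c + nh4_c", True, "Phenylpropanoid/chlorogenate"),
    ("C4H_c", "cinm_c + 2.0 gsh_c + o2_c --> pcouma_c + gssg_c + 2.0 h2o_c",
     True, "Phenylpropanoid/chlorogenate"),
    ("FCL_c", "pcouma_c + coa_c + atp_c --> pcoumcoa_c + adp_c + pi_c",
     True, "Phenylpropanoid/chlorogenate"),
    ("HQT_c", TABLE_REACTIONS["HQT_c"], True, "Phenylpropanoid/chlorogenate"),
    ("C3H_c", "pcoumaroylqnt_c + 2.0 gsh_c + o2_c --> chlorogenate_c + gssg_c + 2.0 h2o_c",
     True, "Phenylpropanoid/chlorogenate"),
    # -- flavonoid / anthocyanin ----------------------------------------
    ("ACC_c", "accoa_c + atp_c + co2_c --> malonylcoa_c + adp_c + pi_c + h_c",
     True, "Flavonoid/anthocyanin"),
    ("CHS_c", "pcoumcoa_c + 3.0 malonylcoa_c --> naringenin_c + 3.0 co2_c + 4.0 coa_c",
     True, "Flavonoid/anthocyanin"),
    ("ANS_c", "naringenin_c + o2_c + nadph_c + h_c --> cyanidin_c + nadp_c + 2.0 h2o_c",
     True, "Flavonoid/anthocyanin"),
    # -- ethylene biosynthesis + cyanide detoxification -----------------
    ("SAMS_c", "met_c + atp_c --> sam_c + adp_c + pi_c",
     True, "Ethylene & cyanide detoxification"),
    ("ACCS_c", "sam_c --> acc_c", True, "Ethylene & cyanide detoxification"),
    ("ACCO_c", "acc_c + o2_c --> ethylene_c + hcn_c + co2_c",
     True, "Ethylene & cyanide detoxification"),
    ("CAS_c", TABLE_REACTIONS["CAS_c"], True, "Ethylene & cyanide detoxification"),
    ("CYSS_c", "ser_c + h2s_c --> cys_c + h2o_c", True, "Ethylene & cyanide detoxification"),
    ("SERS_c", "pep_c + glu_c + nad_c + h2o_c --> ser_c + akg_c + nadh_c + pi_c",
     True, "Ethylene & cyanide detoxification"),
    ("GDH_c", "akg_c + nh4_c + nadh_c + h_c --> glu_c + nad_c + h2o_c",
     True, "Ethylene & cyanide detoxification"),
    # -- cell wall / pectin ---------------------------------------------
    ("PG_c", "pectin_c + h2o_c --> galacturonate_c", True, "Cell wall/pectin degradation"),
    # -- glutathione redox ----------------------------------------------
    ("GR_c", TABLE_REACTIONS["GR_c"], True, "Glutathione redox"),
    # -- maintenance ----------------------------------------------------
    ("NGAM_c", "atp_c + h2o_c --> adp_c + pi_c + h_c", False, "Maintenance"),
    # -- transport ------------------------------------------------------
    ("PYRtm", "pyr_c --> pyr_m", False, "Transport"),
    ("ANTtm", "atp_m + adp_c <=> atp_c + adp_m", False, "Transport"),
    ("PItm", "pi_c <=> pi_m", False, "Transport"),
    ("O2tm", "o2_c <=> o2_m", False, "Transport"),
    ("CO2tm", "co2_m <=> co2_c", False, "Transport"),
    ("H2Otm", "h2o_c <=> h2o_m", False, "Transport"),
    ("Htm", "h_c <=> h_m", False, "Transport"),
    ("QUINtv", "quinate_v --> quinate_c", False, "Transport"),
    ("PECTtv", "pectin_v --> pectin_c", False, "Transport"),
    ("CITtv", "cit_v --> cit_c", False, "Transport"),
    ("CITtm", "cit_c --> cit_m", False, "Transport"),
    ("CGAtv", "chlorogenate_v --> chlorogenate_c", False, "Transport"),
    # -- reserve mobilization pools -------------------------------------
    ("POOL_GLC", " --> glc_c", False, "Pools & exchanges"),
    ("POOL_QUINATE", " --> quinate_v", False, "Pools & exchanges"),
    ("POOL_MET", " --> met_c", False, "Pools & exchanges"),
    ("POOL_PECTIN", " --> pectin_v", False, "Pools & exchanges"),
    ("POOL_NH4", " --> nh4_c", False, "Pools & exchanges"),
    ("POOL_CITRATE", " --> cit_v", False, "Pools & exchanges"),
    ("POOL_CHLOROGENATE", " --> chlorogenate_v", False, "Pools & exchanges"),
    # -- environmental exchanges ----------------------------------------
    ("EX_O2", " --> o2_c", False, "Pools & exchanges"),
    ("EX_CO2", "co2_c --> ", False, "Pools & exchanges"),
    ("EX_H2O", "h2o_c <=> ", False, "Pools & exchanges"),
    ("EX_H", "h_c <=> ", False, "Pools & exchanges"),
    ("SINK_CYANOALA", "cyanoala_c --> ", False, "Pools & exchanges"),
]

_REAL_GENES = {"HQT_c": HQT_GENE, "QDH_c": QDH_GENE}


def _gene_for(reaction_id: str) -> str:
    return _REAL_GENES.get(reaction_id, f"G_{reaction_id}")


def reference_model_table() -> str:
    """The reference model as a tab-delimited reaction table."""
    lines = ["id\tequation\tgpr\tsubsystem"]
    for rid, equation, has_gene, subsystem in _REACTION_ROWS:
        gpr = _gene_for(rid) if has_gene else ""
        lines.append(f"{rid}\t{equation}\t{gpr}\t{subsystem}")
    return "\n".join(lines) + "\n"


def build_reference_model() -> MetabolicModel:
    """Deterministically construct the reduced peach-mesocarp model.

    The returned model carries no RQS and default bounds; prepare it with
    :func:`fruitfba.fba.add_rqs_objective` and
    :func:`fruitfba.fba.apply_ripening_constraints`.
    """
    return parse_reaction_table(reference_model_table(), name="peach_mesocarp_reduced")


# ---------------------------------------------------------------------------
# Scenario expression contrasts
# ---------------------------------------------------------------------------

CONTRAST_IDS = ("MG_E1vsE2", "MG_E3vsE4", "RP_E1vsE2", "RP_E3vsE4")

#: Genes down-regulated per contrast: the published lever layout — a focal
#: gene is "down" in a contrast exactly where its reaction acts as a lever.
_DOWN_GENES: Dict[str, Set[str]] = {
    "MG_E1vsE2": {"G_CAS_c", "G_EPSPS_c", HQT_GENE, QDH_GENE},
    "MG_E3vsE4": {HQT_GENE, QDH_GENE},
    "RP_E1vsE2": {"G_CAS_c", HQT_GENE, "G_PPA_AT_c", QDH_GENE},
    "RP_E3vsE4": {"G_ACO_m", "G_CAS_c", "G_FUM_m", "G_GR_c", HQT_GENE},
}

#: Genes up-regulated per contrast: QDH flips sign after chilling in RP.
_UP_GENES: Dict[str, Set[str]] = {
    "MG_E1vsE2": set(),
    "MG_E3vsE4": set(),
    "RP_E1vsE2": set(),
    "RP_E3vsE4": {QDH_GENE},
}

#: Decoy genes not attached to any reaction, mimicking the transcriptome
#: beyond the model; classes are fixed (seed-independent) by position.
_N_DECOYS = 12

#: Class-conditional log2FC distributions (mean, sd); effect sizes sit
#: >3 sd from the ±1 cutoff so classes are recoverable from draws.
CLASS_DISTRIBUTIONS: Dict[GeneClass, Tuple[float, float]] = {
    GeneClass.DOWN: (-2.0, 0.3),
    GeneClass.UP: (2.0, 0.3),
    GeneClass.NEUTRAL: (0.0, 0.2),
}


def _model_genes() -> List[str]:
    return sorted(_gene_for(rid) for rid, _, has_gene, _ in _REACTION_ROWS if has_gene)


def _decoy_genes() -> List[Tuple[str, GeneClass]]:
    cycle = [GeneClass.DOWN, GeneClass.NEUTRAL, GeneClass.UP]
    return [
        (f"Prupe.0G{900000 + i:06d}", cycle[i % 3])
        for i in range(_N_DECOYS)
    ]


def scenario_gene_classes(contrast_id: str) -> Dict[str, GeneClass]:
    """Generating class of every gene in a scenario contrast (deterministic)."""
    if contrast_id not in CONTRAST_IDS:
        raise KeyError(f"unknown contrast {contrast_id!r}; expected one of {CONTRAST_IDS}")
    classes: Dict[str, GeneClass] = {}
    for gene in _model_genes():
        if gene in _DOWN_GENES[contrast_id]:
            classes[gene] = GeneClass.DOWN
        elif gene in _UP_GENES[contrast_id]:
            classes[gene] = GeneClass.UP
        else:
            classes[gene] = GeneClass.NEUTRAL
    for gene, cls in _decoy_genes():
        classes[gene] = cls
    return classes


def scenario_contrast(contrast_id: str, seed: int = 0) -> ExpressionContrast:
    """Sample a scenario contrast: classes are fixed, log2FCs are seeded draws.

    Up/down genes are flagged significant, neutral genes are not; the same
    seed reproduces the identical table bit for bit.
    """
    classes = scenario_gene_classes(contrast_id)
    rng = np.random.default_rng([seed, CONTRAST_IDS.index(contrast_id)])
    records: Dict[str, Tuple[float, bool]] = {}
    for gene in sorted(classes):
        cls = classes[gene]
        mean, sd = CLASS_DISTRIBUTIONS[cls]
        lfc = float(rng.normal(mean, sd))
        records[gene] = (lfc, cls is not GeneClass.NEUTRAL)
    return ExpressionContrast(contrast_id=contrast_id, records=records)


# ---------------------------------------------------------------------------
# Relative growth rate
# ---------------------------------------------------------------------------


def relative_growth_rate(weight_1: float, weight_2: float,
                         t1: float, t2: float) -> float:
    """Log-scale mass growth per day between two sampling points.

    RGR = (ln w₂ − ln w₁) / (t₂ − t₁), weights in grams, times in days.
    """
    if weight_1 <= 0 or weight_2 <= 0:
        raise ValueError("fruit fresh weights must be positive")
    if t2 <= t1:
        raise ValueError("t2 must be later than t1")
    return (math.log(weight_2) - math.log(weight_1)) / (t2 - t1)
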