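"""Packaged fixtures: published multi-disease candidate and tier tables.

``TABLE_MULTI_DISEASE`` holds the 15 genes reported significant in two or
more neurodegenerative diseases together with the omic-tissue contexts of
their associations; the three ``TIER_*`` lists hold the published 41-novel /
3-known / 115-difficult druggability classification of all 159 candidate
genes.  The druggability, drug-indication and interaction-edge snapshots
returned by :func:`make_fixture_bundle` are *synthetic* reconstructions,
built only to be consistent with those tier lists and with the named
companion-gene relations (e.g. TRIM27 -> MAPK14, CD38 -> OXT); they are not
exports of any curated database.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "TABLE_MULTI_DISEASE",
    "TIER_NOVEL",
    "TIER_KNOWN",
    "TIER_DIFFICULT",
    "FixtureBundle",
    "make_fixture_bundle",
]

#: gene -> (diseases, omic-tissue contexts) for the 15 multi-disease candidates
TABLE_MULTI_DISEASE: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "ARL17B": (("AD", "PD"), ("cerebellum eQTL", "cortex eQTL", "spinalcord eQTL")),
    "KAT8": (
        ("AD", "PD"),
        (
            "cerebellum eQTL", "whole-brain meta-analysis mQTL",
            "cerebellar hemisphere eQTL", "cortex eQTL", "tibial nerve eQTL",
            "skeletal muscle eQTL", "hypothalamus eQTL", "whole-brain eQTL",
            "spinalcord eQTL",
        ),
    ),
    "LRRC37A2": (
        ("AD", "PD"),
        (
            "hippocampus eQTL", "cortex eQTL", "frontal cortex BA9 eQTL",
            "prefrontal cortex eQTL", "caudate basal ganglia eQTL",
            "skeletal muscle eQTL", "multi-ancestry whole-brain meta-analysis eQTL",
            "hypothalamus eQTL", "liver eQTL",
            "anterior cingulate cortex BA24 eQTL", "putamen basal ganglia eQTL",
            "amygdala eQTL", "whole-brain eQTL", "cerebellum eQTL",
            "nucleus accumbens basal ganglia eQTL", "spinalcord eQTL",
            "substantia nigra eQTL",
        ),
    ),
    "KANSL1": (
        ("AD", "PD", "PSP"),
        (
            "whole-brain meta-analysis mQTL", "whole-blood mQTL", "cortex eQTL",
            "multi-ancestry whole-brain meta-analysis eQTL", "spinalcord eQTL",
            "anterior cingulate cortex BA24 eQTL",
        ),
    ),
    "ARL17A": (
        ("AD", "PD", "PSP"),
        (
            "spinalcord eQTL", "amygdala eQTL",
            "multi-ancestry whole-brain meta-analysis eQTL", "hypothalamus eQTL",
            "hippocampus eQTL", "cerebellar hemisphere eQTL", "cortex eQTL",
            "caudate basal ganglia eQTL", "anterior cingulate cortex BA24 eQTL",
            "putamen basal ganglia eQTL", "cerebellum eQTL",
            "nucleus accumbens basal ganglia eQTL",
        ),
    ),
    "PRSS36": (
        ("AD", "PD"),
        (
            "whole-brain meta-analysis mQTL", "cortex eQTL",
            "cerebellar hemisphere eQTL",
            "multi-ancestry whole-brain meta-analysis eQTL", "whole-brain eQTL",
        ),
    ),
    "MAPT": (
        ("AD", "PD", "PSP"),
        ("whole-brain meta-analysis mQTL", "whole-blood mQTL"),
    ),
    "IDUA": (
        ("LBD", "PD"),
        ("whole-brain meta-analysis mQTL", "whole-blood mQTL", "whole-blood eQTL"),
    ),
    "TMEM175": (("LBD", "PD"), ("whole-blood mQTL",)),
    "ARHGAP27": (
        ("AD", "PD", "PSP"),
        (
            "whole-blood mQTL", "whole-blood eQTL",
            "multi-ancestry whole-brain meta-analysis eQTL",
            "caudate basal ganglia eQTL", "nucleus accumbens basal ganglia eQTL",
        ),
    ),
    "CRHR1": (
        ("AD", "PD", "PSP"),
        (
            "whole-brain meta-analysis mQTL", "whole-blood mQTL", "cortex eQTL",
            "skeletal muscle eQTL",
        ),
    ),
    "FMNL1": (
        ("AD", "PSP"),
        ("multi-ancestry whole-brain meta-analysis eQTL", "whole-blood mQTL"),
    ),
    "PLEKHM1": (
        ("PD", "PSP"),
        (
            "cortex eQTL", "frontal cortex BA9 eQTL", "prefrontal cortex eQTL",
            "caudate basal ganglia eQTL", "skeletal muscle eQTL",
            "anterior cingulate cortex BA24 eQTL", "putamen basal ganglia eQTL",
            "whole-brain eQTL",
        ),
    ),
    "WNT3": (
        ("AD", "PD"),
        ("cortex eQTL", "skeletal muscle eQTL", "tibial nerve eQTL"),
    ),
    "SPPL2C": (("AD", "PD"), ("cerebellum eQTL", "prefrontal cortex eQTL")),
}

TIER_NOVEL = (
    "ADAM10", "SNCA", "EGFR", "POU5F1", "STK39", "INPP5D", "CRHR1", "APH1B",
    "MINK1", "CLU", "CR1", "ACE", "CD38", "RABEP1", "ERCC2", "KAT8", "ITGAX",
    "GAK", "STX4", "EPHB4", "EPHA1", "GPNMB", "STAG3", "CHRNE", "NDUFS2",
    "FCER1G", "VKORC1", "DNTT", "CKM", "HSD3B7", "BST1", "STX1B", "PSMC3",
    "CDSN", "MICB", "MS4A2", "PSORS1C1", "EPHX2", "SLC44A4", "MAT1A", "FBXL19",
)

TIER_KNOWN = ("MAPT", "KCNN4", "ADORA2B")

TIER_DIFFICULT = (
    "TRIM27", "PPP4C", "SPI1", "EFNA3", "KIF1C", "WNT3", "CD2AP", "CCNE2",
    "KCTD13", "C9orf72", "SRCAP", "CELF1", "HIP1R", "GRN", "APOC2", "ARHGAP27",
    "MEPCE", "LRRFIP2", "COPS6", "GIGYF1", "BCKDK", "POLR2E", "EFNA4", "DYDC1",
    "ATF6B", "LLGL1", "MTMR2", "GPC2", "LRRC37A", "ARL17B", "INO80E", "SNX31",
    "CEACAM19", "DGKQ", "NUP42", "LRRC37A2", "KANSL1", "ARL17A", "ANXA11",
    "TSPAN14", "CASTOR3", "ZNF232", "ZNF45", "TSBP1", "TREM2", "PRSS36",
    "IDUA", "CCDC158", "CCDC189", "ZSWIM7", "PLEKHM1", "STH", "PVRIG", "YPEL3",
    "MMRN1", "SPPL2C", "SCIMP", "PILRB", "PILRA", "LACTB", "FMNL1", "APOC4",
    "ZNF646", "CPSF3", "ZSCAN9", "ZKSCAN3", "TREML2", "EPDR1", "UFSP1",
    "FAM131B", "TAS2R60", "USP6NL", "MS4A4A", "CASS4", "G2E3", "SCFD1",
    "PCGF3", "SETD1A", "DCAKD", "ZNF668", "AGFG2", "TMEM175", "TOMM40",
    "TRIM40", "WDR81", "TMEM106B", "FNBP4", "SHROOM3", "CYP21A2", "REXO1",
    "TNXB", "MS4A3", "AIF1", "RAB8B", "ZFP57", "FAM200B", "BTNL2", "IGSF9B",
    "HS3ST1", "ZNF311", "NDUFAF6", "TMEM163", "APOC1", "C17orf107", "EXOC3L2",
    "DYDC2", "DOC2A", "ACMSD", "TRIM31", "PRDM7", "TRIM10", "ZAN", "MS4A6A",
    "CPLX1", "SFTA2",
)

#: druggable companions used by the synthetic network/indication snapshots
_COMPANION_DRUGGABLE = ("MAPK14", "NCSTN", "PSEN1", "PSEN2", "PSENEN", "OXT", "APP")

_INDICATION_ROWS = [
    # known-tier genes: therapeutics approved for a study disease
    ("istradefylline", "ADORA2B", "PD", "approved"),
    ("riluzole", "KCNN4", "ALS", "approved"),
    ("apomorphine", "MAPT", "PD", "approved"),
    ("carbidopa", "MAPT", "PD", "approved"),
    # companion genes with approved NDD therapeutics (proxy targets)
    ("neflamapimod", "MAPK14", "AD", "approved"),
    ("tarenflurbil", "NCSTN", "AD", "approved"),
    ("tarenflurbil", "PSEN1", "AD", "approved"),
    ("tarenflurbil", "PSEN2", "AD", "approved"),
    ("tarenflurbil", "PSENEN", "AD", "approved"),
    ("tarenflurbil", "MAPK14", "AD", "approved"),
    ("semagacestat", "NCSTN", "AD", "approved"),
    ("semagacestat", "PSEN1", "AD", "approved"),
    ("semagacestat", "PSEN2", "AD", "approved"),
    ("semagacestat", "PSENEN", "AD", "approved"),
    ("semagacestat", "MAPK14", "AD", "approved"),
    ("avagacestat", "NCSTN", "AD", "approved"),
    ("avagacestat", "PSEN1", "AD", "approved"),
    ("avagacestat", "PSEN2", "AD", "approved"),
    ("avagacestat", "PSENEN", "AD", "approved"),
    ("avagacestat", "MAPK14", "AD", "approved"),
    # novel-tier genes: drugs exist but only non-NDD approvals
    ("glembatumumab vedotin", "GPNMB", "cancer", "approved"),
    ("daratumumab", "CD38", "cancer", "approved"),
    ("riluzole", "SNCA", "AD", "trial"),  # trials never promote to known
]

_EDGE_ROWS = [
    # regulator, target, relation
    ("TRIM27", "MAPK14", "down-regulates"),
    ("CD38", "OXT", "up-regulates"),
    ("NCSTN", "APH1B", "forms-complex"),
    ("PSEN1", "APH1B", "forms-complex"),
    ("PSEN2", "APH1B", "forms-complex"),
    ("PSENEN", "APH1B", "forms-complex"),
    ("ADAM10", "APP", "down-regulates"),
    ("GAK", "SNCA", "unknown"),
]


@dataclass
class FixtureBundle:
    """Snapshot tables sufficient to exercise the downstream triage stages."""

    table2: pd.DataFrame
    table3: dict[str, tuple[str, ...]]
    druggable: set[str] = field(default_factory=set)
    indications: pd.DataFrame = None
    edges: pd.DataFrame = None
    aliases: dict[str, str] = field(default_factory=dict)

    @property
    def all_genes(self) -> tuple[str, ...]:
        return tuple(
            self.table3["novel"] + self.table3["known"] + self.table3["difficult"]
        )

    def expand_table2(self) -> pd.DataFrame:
        """One association row per (gene, disease, omic-tissue context)."""
        rows = []
        for _, r in self.table2.iterrows():
            for d in r["diseases"]:
                for om in r["omics"]:
                    rows.append({"gene": r["gene"], "disease": d, "omic_tissue": om})
        return pd.DataFrame(rows, columns=["gene", "disease", "omic_tissue"])


def make_fixture_bundle() -> FixtureBundle:
    """Build the packaged fixture bundle (fresh copies on every call)."""
    table2 = pd.DataFrame(
        [
            {"gene": g, "diseases": diseases, "omics": omics}
            for g, (diseases, omics) in TABLE_MULTI_DISEASE.items()
        ]
    )
    table3 = {
        "novel": tuple(TIER_NOVEL),
        "known": tuple(TIER_KNOWN),
        "difficult": tuple(TIER_DIFFICULT),
    }
    druggable = set(TIER_NOVEL) | set(TIER_KNOWN) | set(_COMPANION_DRUGGABLE)
    indications = pd.DataFrame(
        _INDICATION_ROWS, columns=["drug", "gene", "disease", "approval_status"]
    )
    edges = pd.DataFrame(_EDGE_ROWS, columns=["regulator", "target", "relation"])
    edges["source"] = "curated-snapshot"
    return FixtureBundle(
        table2=table2,
        table3=table3,
        druggable=druggable,
        indications=indications,
        edges=edges,
    )
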