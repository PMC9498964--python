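"""Minimal pathway node maps for the gene + metabolite overlay tables.

Node ids follow the KEGG convention (hsa gene entries, C-number compounds)
for glycolysis/gluconeogenesis (hsa00010) and the citrate cycle (hsa00020).
Each node maps to the gene symbols or compound names that carry its value;
the maps are intentionally small — enough to tile the core of each pathway —
and are versioned with the package rather than fetched.
"""

from __future__ import annotations

GLYCOLYSIS_NODES: dict[str, list[str]] = {
    # gene nodes (enzymes), keyed by KEGG hsa entry of a representative gene
    "hsa:3098": ["HK1", "HK2", "HK3"],          # hexokinase
    "hsa:2821": ["GPI"],                          # glucose-6-phosphate isomerase
    "hsa:5211": ["PFKL", "PFKM", "PFKP"],       # phosphofructokinase
    "hsa:226": ["ALDOA", "ALDOB", "ALDOC"],     # aldolase
    "hsa:7167": ["TPI1"],                         # triosephosphate isomerase
    "hsa:2597": ["GAPDH"],                        # GAPDH
    "hsa:5230": ["PGK1", "PGK2"],                # phosphoglycerate kinase
    "hsa:5223": ["PGAM1", "PGAM2"],              # phosphoglycerate mutase
    "hsa:2023": ["ENO1", "ENO2", "ENO3"],       # enolase
    "hsa:5315": ["PKM", "PKLR"],                 # pyruvate kinase
    "hsa:3939": ["LDHA", "LDHB"],                # lactate dehydrogenase
    # compound nodes
    "cpd:C00031": ["glucose"],
    "cpd:C00668": ["G6P"],
    "cpd:C00354": ["F16BP"],
    "cpd:C00111": ["DHAP"],
    "cpd:C00197": ["3PG"],
    "cpd:C00074": ["PEP"],
    "cpd:C00022": ["pyruvate"],
    "cpd:C00186": ["lactate"],
}

TCA_NODES: dict[str, list[str]] = {
    "hsa:1431": ["CS"],                           # citrate synthase
    "hsa:50": ["ACO1", "ACO2"],                  # aconitase
    "hsa:3417": ["IDH1", "IDH2", "IDH3A"],      # isocitrate dehydrogenase
    "hsa:4967": ["OGDH"],                         # 2-oxoglutarate dehydrogenase
    "hsa:8802": ["SUCLG1", "SUCLA2"],            # succinyl-CoA ligase
    "hsa:6389": ["SDHA", "SDHB", "SDHC", "SDHD"],  # succinate dehydrogenase
    "hsa:2271": ["FH"],                           # fumarase
    "hsa:4190": ["MDH1", "MDH2"],                # malate dehydrogenase
    "cpd:C00158": ["citrate"],
    "cpd:C00417": ["aconitate"],
    "cpd:C00026": ["aKG"],
    "cpd:C00042": ["succinate"],
    "cpd:C00122": ["fumarate"],
    "cpd:C00149": ["malate"],
    "cpd:C00036": ["oxaloacetate"],
    "cpd:C00025": ["glutamate"],
}

PATHWAYS: dict[str, dict[str, list[str]]] = {
    "glycolysis": GLYCOLYSIS_NODES,
    "tca": TCA_NODES,
}

#: canonical glycolysis gene symbols, used by the expression simulator
GLYCOLYSIS_GENES: list[str] = sorted(
    {
        gene
        for node_id, members in GLYCOLYSIS_NODES.items()
        if node_id.startswith("hsa:")
        for gene in members
    }
)
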