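"""Bundled parameter tables for the yeast glycolysis network.

Molecular weights (g/mol) are literature values: monoisotopic-ish small-
molecule weights for metabolites and UniProt subunit masses for the
S. cerevisiae enzymes.  Turnover numbers are literature-typical magnitudes
(10–10³ 1/s) per isoenzyme.  Both tables are defaults that a user-supplied
override file can replace; entries are keyed by upper-cased id.
"""

#: g/mol
MOLECULAR_WEIGHTS: dict[str, float] = {
    # metabolites
    "GLC": 180.16,       # D-glucose
    "ATP": 507.18,
    "ADP": 427.20,
    "G6P": 260.14,       # glucose 6-phosphate
    "F6P": 260.14,       # fructose 6-phosphate
    "F16BP": 340.12,     # fructose 1,6-bisphosphate
    "DHAP": 170.06,      # dihydroxyacetone phosphate
    "GAP": 170.06,       # glyceraldehyde 3-phosphate
    "NAD": 663.43,
    "NADH": 665.44,
    "BPG": 266.04,       # 1,3-bisphosphoglycerate
    "P3G": 186.06,       # 3-phosphoglycerate
    "P2G": 186.06,       # 2-phosphoglycerate
    "PEP": 168.04,       # phosphoenolpyruvate
    "PYR": 88.06,        # pyruvate
    "G3P": 172.07,       # glycerol 3-phosphate
    "GLY": 92.09,        # glycerol
    "G1P": 260.14,       # glucose 1-phosphate
    "UTP": 484.14,
    "UDPG": 566.30,      # UDP-glucose
    "T6P": 422.28,       # trehalose 6-phosphate
    "TRH": 342.30,       # trehalose
    "GLYCOGEN": 5000.0,  # growing glucan chain, coarse sphere
    # glycolytic enzymes (subunit masses)
    "HXK1": 53738.0, "HXK2": 53944.0, "GLK1": 55377.0,
    "PGI1": 61299.0,
    "PFK": 107000.0,     # PFK1/PFK2 heterocomplex, coarse single species
    "FBA1": 39621.0,
    "TPI1": 26795.0,
    "TDH1": 35750.0, "TDH2": 35847.0, "TDH3": 35838.0,
    "PGK1": 44738.0,
    "GPM1": 27608.0,
    "ENO1": 46816.0, "ENO2": 46914.0,
    "CDC19": 54545.0,    # pyruvate kinase 1
    "GPD1": 42868.0,     # glycerol-3-phosphate dehydrogenase
    "RHR2": 28101.0,     # glycerol-3-phosphatase
    "PGM1": 63089.0,     # phosphoglucomutase
    "UGP1": 55989.0,     # UDP-glucose pyrophosphorylase
    "TPS1": 56147.0,     # trehalose-6-phosphate synthase
    "TPS2": 102940.0,    # trehalose-6-phosphatase
    "GSY2": 80108.0,     # glycogen synthase
}

#: 1/s, per isoenzyme (literature-typical magnitudes)
TURNOVER_NUMBERS: dict[str, float] = {
    "HXK1": 200.0, "HXK2": 250.0, "GLK1": 100.0,
    "PGI1": 900.0,
    "PFK": 200.0,
    "FBA1": 100.0,
    "TPI1": 1000.0,
    "TDH1": 100.0, "TDH2": 100.0, "TDH3": 120.0,
    "PGK1": 800.0,
    "GPM1": 400.0,
    "ENO1": 80.0, "ENO2": 90.0,
    "CDC19": 250.0,
    "GPD1": 70.0,
    "RHR2": 100.0,
    "PGM1": 400.0,
    "UGP1": 100.0,
    "TPS1": 50.0,
    "TPS2": 50.0,
    "GSY2": 50.0,
}

#: mmol/l after the below-1-mmol/l rescaling of the source kinetic model.
#: Only pyruvate (0.2), trehalose (0.015) and NADH (0.086) are printed
#: values; every other entry is a documented approximation (approx=True on
#: the resulting species).
INITIAL_CONCENTRATIONS: dict[str, float] = {
    "GLC": 0.90,
    "ATP": 0.60,
    "ADP": 0.20,
    "G6P": 0.10,
    "F6P": 0.05,
    "F16BP": 0.10,
    "DHAP": 0.10,
    "GAP": 0.05,
    "NAD": 0.30,
    "NADH": 0.086,
    "BPG": 0.0017,
    "P3G": 0.05,
    "P2G": 0.03,
    "PEP": 0.05,
    "PYR": 0.20,
    "G3P": 0.05,
    "GLY": 0.10,
    "G1P": 0.02,
    "UTP": 0.20,
    "UDPG": 0.05,
    "T6P": 0.01,
    "TRH": 0.015,
    "GLYCOGEN": 0.0017,
}

#: Printed (non-approximate) initial concentrations.
EXACT_CONCENTRATIONS = {"PYR", "TRH", "NADH"}

#: mmol/l; enzyme copy numbers per attolitre follow from these (× ~602).
ENZYME_CONCENTRATIONS: dict[str, float] = {
    "HXK1": 0.0050, "HXK2": 0.0100, "GLK1": 0.0033,
    "PGI1": 0.0117,
    "PFK": 0.0083,
    "FBA1": 0.0166,
    "TPI1": 0.0166,
    "TDH1": 0.0050, "TDH2": 0.0050, "TDH3": 0.0166,
    "PGK1": 0.0133,
    "GPM1": 0.0133,
    "ENO1": 0.0083, "ENO2": 0.0166,
    "CDC19": 0.0133,
    "GPD1": 0.0050,
    "RHR2": 0.0050,
    "PGM1": 0.0033,
    "UGP1": 0.0033,
    "TPS1": 0.0033,
    "TPS2": 0.0033,
    "GSY2": 0.0033,
}
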