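"""Physical constants (CODATA 2018) and shared defaults."""

BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol

#: Partial specific volume of an average protein in solution, cm^3/g.
#: Applied to every molecule (metabolites included), since all species are
#: modelled as spheres derived from their molecular weight.
DEFAULT_VBAR = 0.73

#: Surface-to-surface distance (Å) below which binding is certain in every
#: distance-dependent interaction law.
CONTACT_CERTAIN_DISTANCE = 5.0
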