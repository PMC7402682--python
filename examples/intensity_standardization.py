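"""Standardize heterogeneous compound concentrations into one intensity.

Each compound is expressed as log10(observed concentration / regulatory
quality criterion): 0 means exactly at the criterion, +1 one order of
magnitude above it. An observation reporting several compounds takes the
intensity of its strongest compound.
"""

from befmeta import CompoundLevel, ecd_intensity, max_intensity

levels = [
    CompoundLevel("Cu", conc_treatment=120.0, conc_criteria=1.0, units="mg/kg",
                  criteria_source="ECHA"),
    CompoundLevel("Zn", conc_treatment=30.0, conc_criteria=10.0, units="mg/kg",
                  criteria_source="USEPA"),
    CompoundLevel("atrazine", conc_treatment=0.06, conc_criteria=0.6,
                  units="ug/L", criteria_source="USEPA"),
]

for lv in levels:
    print(f"{lv.compound:>9}: intensity = {ecd_intensity(lv):+.3f}")

intensity, compound = max_intensity(levels)
print(f"\nobservation intensity = {intensity:+.3f} (driven by {compound})")
# Cu sits two orders of magnitude above its quality criterion (+2.08) and
# defines the observation's intensity; atrazine is below its criterion
# (negative value), i.e. at a level considered safe.
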