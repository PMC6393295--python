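"""Published benchmark values for PhNSun6 assays.

These are the reported steady-state constants and melting midpoints
for the characterized P. horikoshii tRNAs; the package uses them as
generating parameters for simulation-and-recovery runs and as the
expected values those runs should reproduce.
"""

from __future__ import annotations

from .kinetics import MichaelisMentenParams

__all__ = ["KINETIC_CONSTANTS", "MELTING_POINTS_C"]

#: Reported Michaelis-Menten constants (kcat min^-1, Km uM) of PhNSun6
#: for selected substrates, at the standard 100 nM enzyme design.  The
#: Km of the Cys substrate is reported only as belonging to the
#: "approximately 0.5 uM" class shared by the four initial substrates.
KINETIC_CONSTANTS: dict[str, MichaelisMentenParams] = {
    "Thr(CGU)": MichaelisMentenParams(kcat=4.30, km=0.43, enzyme_conc_nM=100.0),
    "Thr(CGU)-U73G": MichaelisMentenParams(kcat=2.11, km=0.59, enzyme_conc_nM=100.0),
    "Cys(GCA)": MichaelisMentenParams(kcat=3.04, km=0.50, enzyme_conc_nM=100.0),
}

#: Reported melting midpoints (degC) of the eleven PhNSun6 substrates,
#: as (unmodified, m5C72-modified) pairs.
MELTING_POINTS_C: dict[str, tuple[float, float]] = {
    "Thr(CGU)": (66.3, 67.3),
    "Thr(GGU)": (61.3, 62.3),
    "Thr(UGU)": (69.3, 71.3),
    "Cys(GCA)": (61.2, 62.8),
    "Ser(UGA)": (62.7, 64.7),
    "Ser(CGA)": (65.8, 66.8),
    "Ser(GGA)": (67.5, 69.5),
    "Ser(GCU)": (65.2, 66.8),
    "Asn(GUU)": (71.6, 73.0),
    "Asp(GUC)": (73.2, 76.2),
    "Arg(GCG)": (68.0, 68.7),
}
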