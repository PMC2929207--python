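"""Annotate observed peak masses with theoretical tryptic peptides at 2 ppm.

Digests a protein in silico (trypsin, up to 2 missed cleavages, fixed
carboxymethyl-Cys, variable Met oxidation) and matches observed [M+H]+
masses against the theoretical peptide masses with a 2 ppm cutoff.
"""

from peptidiff import match_masses, mono_mass, make_peptide, tryptic_digest
from peptidiff.peptides import PROTON

# beta-2-microglobulin, mature chain
B2M = (
    "IQRTPKIQVYSRHPAENGKSNFLNCYVSGFHPSDIEVDLLKNGERIEKVEHSDLSFSKDWSFYLLYYTEFTPTEKDEYACRVNHVTLSQPKIVKWDRDM"
)

candidates = tryptic_digest(B2M, max_missed=2, source_protein="B2MG_HUMAN")
print(f"{len(candidates)} candidate peptides (with modification variants)")

# pretend the instrument saw the VEHSDLSFSK peak, 1 ppm high, plus noise
target = make_peptide("VEHSDLSFSK").mz_1plus
observed = [target * (1 + 1e-6), 1500.1234]
matches = match_masses(observed, candidates, cutoff_ppm=2.0)
for m in matches:
    print(
        f"observed {m.observed_mz:.4f} -> {m.peptide.sequence} "
        f"({m.peptide.source_protein}, {m.peptide.missed_cleavages} missed) "
        f"error {m.error_ppm:+.2f} ppm"
    )
print(f"unmatched masses: {len(observed) - len({m.observed_mz for m in matches})}")
print(f"neutral monoisotopic mass of VEHSDLSFSK: {mono_mass('VEHSDLSFSK'):.4f} u "
      f"([M+H]+ = {mono_mass('VEHSDLSFSK') + PROTON:.4f})")
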