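"""Estimating the credit of ecological interactions from species lists.

The credit cashable by a reintroduction is the number of plant species
present in the focal area that are documented interaction partners of the
animal: the intersection of a flora list with a diet reference.  Uses the
packaged 12-species toy fixture (synthetic, with documented ground truth).
"""

from ecocredit import count_flagged, estimate_credit, read_flora, read_reference
from ecocredit.datasets import toy_diet_path, toy_flora_path

flora = read_flora(toy_flora_path())
reference = read_reference(toy_diet_path())

est = estimate_credit(flora, reference)
flagged = count_flagged(est.eligible_species, flora, "large_seeded_reliant")

print(f"flora species:               {len(flora)}")
print(f"diet reference species:      {len(reference.plant_ids)}")
print(f"credit of interactions:      {est.credit0}")
print(f"large-seeded reliant, of it: {flagged}")
print(f"eligible species:            {sorted(est.eligible_species)}")
print(
    "\nThe credit (here 8) is the ceiling on how many interactions this"
    "\nreintroduction can restore; the flagged count identifies the subset"
    "\nwhose recruitment depends on the animal (dispersal-reliant trees)."
)
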