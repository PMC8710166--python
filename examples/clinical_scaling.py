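"""Scale the tolerated chamber dose to a clinical moxibustion room.

A 4 x 3 x 3.6 m treatment room is 216x the volume of the 0.2 m3 exposure
chamber, so the room's 2-hour stick consumption (216 g) produces the same
smoke concentration as burning 1 g in the chamber.  The safety margin is
the tolerated chamber burn expressed in multiples of that equivalent.
"""

from moxatox import clinical_safety_margin, volume_ratio
from moxatox.dosimetry import ClinicalRoom, ExposureChamber, clinical_equivalent_mass

room = ClinicalRoom()
chamber = ExposureChamber(volume_m3=0.2)

print(f"room volume:              {room.volume_m3:.1f} m3")
print(f"chamber volume:           {chamber.volume_m3:.1f} m3")
print(f"volume ratio:             {volume_ratio(room, chamber):.0f} : 1")
print(f"clinical equivalent mass: {clinical_equivalent_mass(room, chamber):.2f} g in-chamber")
tolerated = 68.68  # g of sticks: the highest burn with zero mortality
print(f"safety margin:            {clinical_safety_margin(tolerated, room, chamber):.2f}x")
print("\nThe tolerated exposure is ~69x the smoke concentration of a standard")
print("2-hour clinical moxibustion session in such a room.")
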