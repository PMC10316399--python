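"""Partial density profile of a ganglioside moiety along the membrane normal.

Builds a synthetic multi-frame system in which Sia3 atoms sit in a narrow
band around z = 6 nm (emulating the sialic acid layer above a bilayer
midplane) and water fills a slab above it, then computes the peak-normalised
partial density profile of each selection along z.  The printed peak
positions show where each group sits; the Sia band is recovered at its
planted position.
"""

import numpy as np

from gslnano import density_profile, make_membrane_fixture

coords, topology, moieties, _ = make_membrane_fixture(
    n_gsl=2, species="GM1", planted_bonds=[("Sia3", "Sia3", 3)],
    n_water=20, box=12.0, seed=4,
)
box = np.full(3, 12.0)
labels = moieties.labels.to_numpy()

for label in ("Sia3", "water"):
    selection = np.flatnonzero(labels == label)
    profile = density_profile(coords, box, selection, axis="z", n_bins=40)
    peak = profile.loc[profile["density"].idxmax(), "bin_center_nm"]
    occupied = (profile["density"] > 0.5).sum() * (12.0 / 40)
    print(f"{label:>6s}: {len(selection):3d} atoms, density peak at z = "
          f"{peak:.2f} nm, half-maximum width ~{occupied:.2f} nm")

print("\n(the fixture plants the bond sites at z = 6 nm and the free water "
      "slab at z = 4 nm; the profiles recover those positions)")
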