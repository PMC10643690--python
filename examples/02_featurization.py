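"""Molecule fingerprints, image preprocessing and molecule-grouped splits.

Shows the two fingerprint variants (1024-bit Morgan; 8192-bit combined
Morgan/RDKit max), the 16-to-8-bit conversion with hot-pixel clipping, and
a scaffold split keeping shared ring systems in one set.
"""

import numpy as np

from cellmol.fingerprints import (bemis_murcko_scaffold, combined_fingerprint,
                                  morgan_fingerprint)
from cellmol.preprocess import convert_16to8
from cellmol.records import MoleculeRecord
from cellmol.splits import make_split

aspirin = "CC(=O)Oc1ccccc1C(=O)O"
fp = morgan_fingerprint(aspirin)
combo = combined_fingerprint(aspirin)
print(f"aspirin Morgan fp: {fp.size} bits, {fp.sum()} set")
print(f"aspirin combined fp: {combo.size} bits, {combo.sum()} set")
print(f"aspirin scaffold: {bemis_murcko_scaffold(aspirin)}")

# hot pixels are clipped before rescaling to 8 bits
rng = np.random.default_rng(0)
img = rng.integers(200, 800, size=(1, 64, 64)).astype(np.uint16)
img[0, 0, :8] = 65535  # a streak of saturated pixels
naive = convert_16to8(img, clip_fraction=0.0)
clipped = convert_16to8(img, clip_fraction=0.01)
print(f"16->8 bit, body pixel: naive rescale -> {naive[0, 32, 32]}, "
      f"with 1% clip -> {clipped[0, 32, 32]} "
      "(clipping keeps the dynamic range for real signal)")

smiles = ["Cc1ccccc1", "CCc1ccccc1", "c1ccncc1", "CCc1ccncc1",
          "C1CCCCC1", "CC1CCCCC1", "CCO", "CCCO", "CCCCO", "CCCCCO"]
mols = [MoleculeRecord(f"m{i}", smiles=s,
                       scaffold_key=bemis_murcko_scaffold(s))
        for i, s in enumerate(smiles)]
split = make_split(mols, mode="scaffold", seed=0)
for set_name in ("train", "valid", "test"):
    members = split.members(set_name)
    print(f"{set_name}: {[m for m in sorted(members)]}")
# molecules sharing a scaffold (e.g. the two benzenes) are never separated
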