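"""Generate a small synthetic paired screen and inspect its structure.

Each molecule gets a latent phenotype; its fingerprint is a thresholded
random projection of that latent and each microscopy view renders the
latent as Gaussian blobs plus pixel noise, so the two modalities share a
decodable signal.
"""

import numpy as np

from cellmol.synthetic import (SyntheticSpec, generate_label_matrix,
                               generate_paired_dataset)

spec = SyntheticSpec(n_molecules=20, views_per_molecule=3, latent_dim=8,
                     noise_sd=0.2, seed=42)
images, molecules, pairing, truth = generate_paired_dataset(spec)

print(f"{len(images)} image views of {len(molecules)} molecules")
print(f"image tensor: {images[0].pixels.shape} {images[0].pixels.dtype} "
      f"(plate {images[0].plate_id})")
print(f"fingerprint: {molecules[0].fp_custom.size} bits, "
      f"{molecules[0].fp_custom.sum()} set")
print(f"MoA classes: {sorted(int(c) for c in pairing['moa_class'].unique())}")

# same-molecule views differ only by noise: their correlation is high
a, b = images[0].pixels.astype(float), images[1].pixels.astype(float)
c, d = images[0].pixels.astype(float), images[3].pixels.astype(float)
same = np.corrcoef(a.ravel(), b.ravel())[0, 1]
diff = np.corrcoef(c.ravel(), d.ravel())[0, 1]
print(f"pixel correlation same molecule {same:.3f} vs different {diff:.3f}")
# expect same >> diff: the latent, not the noise, shapes the image

labels = generate_label_matrix(molecules, truth.latents, n_tasks=4,
                               sparsity=0.7, seed=0)
print(f"label matrix {labels.shape}, "
      f"{100 * labels.isna().to_numpy().mean():.0f}% missing entries")
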