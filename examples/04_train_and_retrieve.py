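"""Contrastively pre-train both encoders on a small synthetic screen and
retrieve structures from images (and vice versa) on held-out molecules.

A smaller, faster cousin of the full benchmark in
cellmol.workflows.run_benchmark; expect a few tens of seconds on one core.
"""

import numpy as np

from cellmol.encoders import ContrastiveModel, EncoderConfig, image_encode, \
    structure_encode
from cellmol.evaluation import retrieval_eval
from cellmol.preprocess import channel_stats, convert_16to8, normalize_images
from cellmol.synthetic import SyntheticSpec, generate_paired_dataset
from cellmol.training import TrainConfig, train

spec = SyntheticSpec(n_molecules=120, views_per_molecule=2, latent_dim=8,
                     noise_sd=0.2, seed=0)
images, molecules, pairing, truth = generate_paired_dataset(spec)

test_mols = {m.molecule_id for m in molecules[-40:]}  # 40 held out
train_recs = [r for r in images if r.molecule_id not in test_mols]
test_recs = [r for r in images if r.molecule_id in test_mols
             and r.view_index == 0]

pix_train = np.stack([convert_16to8(r.pixels) for r in train_recs])
pix_test = np.stack([convert_16to8(r.pixels) for r in test_recs])
means, sds = channel_stats(pix_train)
pix_train, pix_test = (normalize_images(p, means, sds)
                       for p in (pix_train, pix_test))

fp_of = {m.molecule_id: m.fp_custom.astype(float) for m in molecules}
cfg = EncoderConfig(embed_dim=32, image_channels=5, image_width=96,
                    image_depth=1, patch_size=8, image_hw=(32, 32),
                    fp_bits=1024, structure_hidden=(128,))
model = ContrastiveModel(cfg, seed=0)
result = train(model, pix_train,
               np.stack([fp_of[r.molecule_id] for r in train_recs]),
               TrainConfig(base_lr=2e-3, batch_size=64, epochs=10 ** 6,
                           max_steps=250, tau_inv=14.3, seed=0))
print(f"loss: {result.loss_trace[0]:.2f} -> {result.loss_trace[-1]:.2f} "
      f"over {len(result.loss_trace)} steps")

img_embs, _ = image_encode(pix_test, model.image_encoder,
                           ids=[r.image_id for r in test_recs])
ids = sorted(test_mols)
mol_embs, _ = structure_encode(np.stack([fp_of[m] for m in ids]),
                               model.structure_encoder, ids=ids)
mapping = {r.image_id: r.molecule_id for r in test_recs}
s_rep, i_rep = retrieval_eval(img_embs, mol_embs, mapping)
chance = 100.0 / len(ids)
for rep in (s_rep, i_rep):
    lo, hi = rep.topk_ci[1]
    print(f"{rep.direction}: top-1 {rep.topk[1]:.1f}% "
          f"(chance {chance:.1f}%, 95% CI [{lo:.1f}, {hi:.1f}]), "
          f"top-5 {rep.topk[5]:.1f}%")
# top-1 well above chance means the two encoders share a latent geometry
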