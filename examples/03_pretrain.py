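"""Pre-train the two-branch model on a small synthetic corpus.

Prints the loss trajectory and the mean positive-pair similarity before and
after training: contrastive pre-training should pull each molecule's two
views together on the unit sphere.
"""

import fragclr as fc
from fragclr.encoders import EncoderConfig, TwoBranchModel
from fragclr.training import (
    PretrainConfig, filter_corpus, mean_positive_pair_similarity, pretrain,
)

smiles = fc.random_molecules(
    fc.FixtureSpec(n_molecules=40, seed=7, max_heavy_atoms=8,
                   ring_probability=0.15)
)
corpus = [fc.parse_smiles(s) for s in smiles]

cfg = PretrainConfig(
    batch_size=8, epochs=5, seed=0,
    encoder=EncoderConfig(embedding_dim=32, fusion_layers=1,
                          projection_hidden_dim=32, seed=0),
)
result = pretrain(corpus, cfg)

print(f"initial train loss: {result.initial_train_loss:.2f}")
for ep, row in enumerate(result.train_losses):
    print(f"  epoch {ep}: total {row['total']:.2f} "
          f"(L_clr {row['L_clr']:.2f}, L_sim {row['L_sim']:.3f})")
print(f"best epoch by validation loss: {result.best_epoch}")

pairs, _ = filter_corpus(corpus)
init = mean_positive_pair_similarity(TwoBranchModel(cfg.encoder), pairs)
trained = mean_positive_pair_similarity(result.model, pairs)
print(f"mean <p_mol, p_fv>: {init:.3f} at initialisation, "
      f"{trained:.3f} after pre-training (closer to 1 = better aligned)")
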