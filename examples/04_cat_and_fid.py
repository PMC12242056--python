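"""Score generated images semantically (CAT) and distributionally (FID).

CAT counts how many of the five annotation tags of each ground-truth test
image the generated image matches (2 broad + 1 specific + 1 background +
1 attribute); a 200-image set has a 1000-point ceiling.  FID compares
Gaussian fits of feature clouds; for two univariate Gaussians it reduces
to (mu1-mu2)^2 + (sigma1-sigma2)^2.
"""

import numpy as np

from eeg2img import cat_score, fid, make_concept_bank, make_tag_cards

bank = make_concept_bank(K=400, D_img=16, n_test=200, seed=0)
cards = make_tag_cards(bank, rng=np.random.default_rng(0))
print(f"{len(cards)} test images x 5 tags = {5 * len(cards)} points ceiling")

perfect = cat_score([set(c.tags) for c in cards], cards)
print(f"perfect generator: CAT {perfect.total} / {perfect.max_possible}")

partial = cat_score([{c.broad_1, c.specific} if i % 2 == 0 else set()
                     for i, c in enumerate(cards)], cards)
print(f"half-right generator: CAT {partial.total} / {partial.max_possible}")

rng = np.random.default_rng(1)
real = rng.standard_normal((100_000, 1))            # N(0, 1)
gen = 2.0 * rng.standard_normal((100_000, 1))       # N(0, 4)
print(f"FID N(0,1) vs N(0,4): {fid(real, gen).value:.3f} "
      f"(closed form: (1-2)^2 = 1)")
print(f"FID of a set against itself: {fid(real, real).value:.2e}")
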