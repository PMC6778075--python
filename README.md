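# tilebayes

Uncertainty-aware classification of histopathology tiles with a Bayesian
dropout CNN — and the three workflows that uncertainty unlocks: efficient
active annotation, detection of mislabelled training tiles, and tile-based
whole-slide segmentation.

## Who this is for

Digital-pathology and biomedical-imaging groups that classify small tissue
tiles (e.g. the colorectal collections of 8 classes × 625 tiles of 150×150
px) and need each prediction to come with a trustworthy uncertainty, so a
pathologist knows which tiles to double-check, which classes to annotate
next, and which training labels to distrust.

## The model

A compact residual CNN trunk feeds two 32-unit fully connected layers, each
with dropout at rate 0.5, ending in an auxiliary and a final softmax head.
Training minimises the weighted categorical cross-entropy

    L(o) = 0.9 · CE(final) + 0.1 · CE(aux),
    CE(p) = −Σ_y δ(y_o = y) ln p(y | o, ω̂)

with Adam, batches of 32, and a learning rate cut ×0.1 whenever validation
accuracy plateaus.

Keeping dropout active at prediction time makes the network approximately
Bayesian: each stochastic pass t samples weights ω̂_t ~ q(ω), and

    P(y* | o, D) ≈ (1/T) Σ_t P(y* | o, ω̂_t),   T = 50 by default.

From the T×M matrix of per-pass probabilities two uncertainties are derived
(both in nats):

* **Entropy H** = H[P(y*|o,D)] — total predictive uncertainty;
* **BALD** = H[P(y*|o,D)] − (1/T) Σ_t H[P(y*|o,ω̂_t)] — the mutual
  information between label and weights, i.e. the epistemic part.

Always 0 ≤ BALD ≤ H ≤ ln M. These drive:

* **Active learning** — start from 40 labelled tiles per class, repeatedly
  acquire the 160 most-uncertain pool tiles and retrain from a fresh
  initialisation;
* **Mislabel detection** — flag tiles misclassified with H below the
  p_m-th percentile of their class's H distribution (union over classes);
* **Segmentation** — cut a slide into 50 px tiles, upscale to the model
  input, classify each by the argmax of its MC mean, stitch class colours,
  and report per-class surface-area percentages.

The network is implemented from scratch in NumPy (im2col convolutions,
batch norm, residual blocks, hand-written backprop), so the package has no
deep-learning-framework dependency.

## Worked example

`examples/01_train_and_uncertainty.py` trains on a synthetic 4-class tile
set whose classes 2 and 3 are nearly indistinguishable (the analogue of
ambiguous tissue pairs such as simple vs complex stroma) and scores
held-out tiles:

```
model: 20872 parameters
held-out accuracy: 1.000
   class   mean H  mean BALD  errors
       0    0.318      0.126       0
       1    0.411      0.178       0
       2    0.460      0.171       0
       3    0.528      0.156       0
```

Mean entropy H is highest for the confusable pair (classes 2 and 3): the
model's uncertainty localises exactly where the class definitions overlap,
even when accuracy is perfect. The other examples demonstrate the
acquisition loop (`02`), planted-noise recovery (`03`, sensitivity 1.000 /
specificity 0.914 at 10% noise) and slide segmentation with exact area
bookkeeping (`04`).

A thin CLI wraps the same functions: `tilebayes simulate | train | predict
| active-learn | find-mislabelled | segment | evaluate` (see `--help`).

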