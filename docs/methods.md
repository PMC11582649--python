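# Methods

This note documents the models, procedures and design choices behind
`tileshot`, in the spirit of the methods documentation of mature
scientific Python packages.

## Problem setting

Given a catalogue of histology image tiles — each with a class label,
optionally a patient of origin, and a pre-computed embedding vector — we
evaluate a vision-language model's ability to classify held-out tiles
when conditioned on labelled exemplar tiles inside the prompt (few-shot
in-context learning), and compare it with classical decision rules on
the same frozen embeddings. No encoder runs inside this package:
embeddings are inputs, aligned row-for-row with the manifest. The
default dimension is 768, the output size of ViT-B-class histopathology
encoders.

## Exemplar retrieval (kNN sampler)

For a target tile t and each label y, the sampler selects the k eligible
candidates maximising cosine similarity to t's embedding. Because the
similarity of each candidate is independent of the others, the top-k
selection is exactly the argmax of the summed similarity over k-subsets;
the test suite verifies this equivalence by exhaustive subset
enumeration on small pools. Eligibility excludes the target itself
and — when patient ids are available on both sides and the exclusion
flag is set (default) — all tiles from the target's patient. A pair with
a missing patient id on either side is treated as different patients.
Ties in similarity are broken by ascending tile id; the choice is
arbitrary but fixed, so runs are reproducible. Within each label,
exemplars are ordered most-similar-first, which is also the order they
appear in the prompt.

The random-sampling arm draws k exemplars per label uniformly without
replacement under the same exclusions, so the two arms differ only in
the selection rule. Whether a random arm should also exclude same-patient
tiles is a genuinely open choice; we exclude, for comparability, and the
run log records the flag.

## Prompt construction

A prompt bundle contains one system part (role framing, a hypothetical-
scenario disclaimer, desired/undesired response pairs, and the JSON
output contract), one user part (label enumeration in label-set order, a
step-wise-reasoning instruction, optional dataset-specific guidelines),
then k rounds of exemplars cycling through the label set — caption
"The following image contains {y}:" immediately before each exemplar
image — and finally the target image after a closing instruction. A
few-shot bundle therefore holds exactly k·|𝒴| + 1 images; with k = 0 the
bundle reduces to the zero-shot form. Caption-before-image was chosen
over label-after-image (both orderings are defensible; the explicit
prefix phrasing won) and is asserted by tests. The prompt texts shipped
under `src/tileshot/templates/` are this package's own wording of those
elements; the dataset-guideline snippet is an illustrative placeholder,
and a SHA-256 hash of all template assets is written into every run log
so results are traceable to exact prompt text.

Answers are parsed from JSON (markdown fences stripped), canonicalized
case-insensitively through an alias map with identity entries, and
classified as `ok`, `failed` (non-JSON or missing answer) or `unmapped`
(an answer matching no label or alias). Certainty scores outside [0, 1]
are clamped with a warning, since no range contract can be enforced on a
free-form model.

## Backends and the mock oracle

Any endpoint satisfying the `VLMBackend` protocol (name, image
capability, `complete_once`) can run the pipeline; completions go
through a retry loop that returns a failure record — never an
exception — after exhausting `max_retries`, so one flaky request cannot
abort a run. Temperature defaults to 0.1: essentially deterministic
decoding for structured classification output. A token-bucket rate
limiter is available for quota-bound endpoints. The HTTP adapter
(`tileshot.http_adapter`) speaks the generic chat-completions JSON form
with base64 PNG images; it is optional and imported nowhere in the test
path.

The mock oracle makes the pipeline testable end to end offline. It
answers a few-shot bundle with the label of the in-context exemplar most
cosine-similar to the target (certainty = similarity mapped to [0, 1]),
and a zero-shot bundle with the target's true label; in both cases the
answer is flipped to a uniformly random other label with probability
`error_rate`. The flip decision derives from a SHA-256 hash of
(seed, target tile, image count), so identical inputs give bit-identical
raw text across processes. Consequences used by the tests: with
`error_rate` 0 on a well-separated fixture, kNN contexts yield accuracy
exactly 1.0 for any k ≥ 1; with vanishing class separation the few-shot
answer follows the class of the globally most similar eligible
candidate, i.e. chance level 1/G on balanced pools; expected accuracy
under the flip channel is 1 − ε. A refusal injector wraps any backend to
return non-JSON refusals for a seeded fraction of targets, exercising
failure accounting.

## Evaluation and the bootstrap

Scoring maps each task to a binary correctness indicator. Failed and
unmapped responses are excluded by default (with counts reported) or
counted as wrong under the alternative policy; both policies are logged
because excluded queries change the effective denominator.

Confidence intervals use the percentile bootstrap: B = 100,000 resamples
of size n with replacement from the pooled outcome vector, the mean of
each resample, and the empirical order statistics at ranks
ceil(α/2·B) and ceil((1−α/2)·B) with α = 0.05. No interpolation is
applied: resampled means of a binary vector live on the lattice {k/n},
and interpolation would fabricate off-lattice values. The resampled mean
is distributed as Binomial(n, p̂)/n, so the bounds converge to exact
binomial quantiles; the tests assert this agreement for randomized
configurations, screening out knife-edge cases where the binomial CDF at
the adjacent lattice point lies within 0.005 of the nominal tail mass —
there the empirical order statistic legitimately lands on either
neighbour depending on the seed. Resampling is pooled by default; a
stratified-by-label variant is available behind a flag. Confusion
matrices (rows = truth), per-label recall, macro recall, and a tidy
cross-run comparison table complete the metrics surface; micro and
macro views are both emitted because "average accuracy across labels" is
ambiguous between them.

## Baselines

`nn_classify` assigns the label of the most cosine-similar training tile
(k = 1 default), with majority voting for larger k; ties break by summed
similarity, then smallest supporting tile id. It agrees exactly with a
brute-force argmax over all similarities in tests.

The linear probe is a single softmax layer trained with Adam
(β₁ = 0.9, β₂ = 0.999), learning rate 0.001, cross-entropy loss, for a
small number of epochs (1/3/5/10 conventional). Weights initialize
seeded uniform in ±1/√dim; bias at zero. Training is full-batch (one
step per epoch) up to 256 tiles — deterministic for the per-task
matched-conditions protocol — and seeded mini-batch above. Inputs are
standardized per feature by default (mean/std stored on the probe), which
makes the fit invariant to a global rescaling of the embeddings. The
epoch-end training loss is recorded; on full-batch convex runs it is
non-increasing. Note that with lr 0.001 and only a handful of samples
and epochs, a per-task matched probe moves little from initialization —
its contract is that its training set equals the few-shot context
exactly, not that it is a strong classifier. Probe checkpoints serialize
to JSON (human-diffable at these sizes).

## Reasoning analysis

Per-task reasoning texts are embedded (contract: deterministic
text → vector; a seeded feature-hashing bag-of-words embedder ships for
offline use — not semantic, but shared vocabulary lands nearby, which is
what cluster analyses need), reduced by PCA to at most 200 components
(capped at the rank bound with a warning), and projected to 2-D by t-SNE
with perplexity 30 and seed 42. The perplexity must satisfy
perplexity < (n−1)/3 or a config error with a suggested value is raised.
Silhouette scores — (b−a)/max(a,b) per point, Euclidean metric,
singletons scored 0 — are computed on the 2-D coordinates (a flag allows
raw-space computation) against both the model's answers and the ground
truth, since either clustering is a defensible target; both are
reported. Term-frequency tables per label stand in for word-cloud
visualisation.

## Synthetic fixtures

The generator draws G orthonormal directions (QR of a seeded Gaussian
matrix, signs fixed) scaled by the separation δ as class centers; each
tile is center + a per-patient offset (Gaussian, scale σ/2) + tile noise
(Gaussian, scale σ). Defaults: two classes, dim 768, δ/σ = 8 (clearly
separated, as distinct tissue classes are in a good embedding space),
ten patients per class, ten tiles each. The patient offset at σ/2 makes
same-patient tiles measurably closer than same-class cross-patient
tiles — enough for leakage to matter, not enough to swamp the class
signal — so the patient-exclusion rule is genuinely exercised. Images
are deterministic class-hued noise PNGs, decorative by design: encoders
never run in tests, keeping the suite fast. Balanced test splits draw
per-class targets seeded and without replacement (30/class for binary
tasks → 60; 15/class for 8-class tasks → 120).

What the fixtures do **not** emulate: real histology texture, stain
variation, label noise, class imbalance, or the heavy-tailed similarity
structure of real embedding spaces. Passing tests therefore demonstrate
the correctness of the machinery (retrieval, ordering, exclusion,
accounting, statistics), not the clinical performance of any model.

## Problem sizes and numerical choices

The test suite runs fixtures of tens to a few hundred tiles, embedding
dimensions 8–768, bootstrap vectors up to n = 1000, and B = 100,000
bootstrap iterations (the setting the CI machinery is specified at —
cheap, since resampling is vectorised). Monotonicity of accuracy in the
shot count is asserted over 20 seeded runs per k ∈ {0, 1, 3, 5, 10}
under an error schedule decreasing linearly from 0.4 at k = 0 to 0 at
k = 10. Cosine similarities are computed in float64 and clipped to
[−1, 1]; embeddings store as little-endian float32.

## Known limitations

- The mock oracle is a similarity rule, not a language model; it cannot
  surface prompt-wording effects, and reasoning texts it emits are
  templated.
- Bootstrap bounds inherit lattice granularity 1/n; at n = 60 adjacent
  printed bounds differ by ~0.017.
- The probe implements exactly one optimizer configuration; learning-rate
  schedules and validation checkpointing used for large-scale training
  are out of scope.
- The hashing text embedder is a stand-in; silhouette magnitudes on real
  model output require a semantic embedder plugged into the
  `TextEmbedder` contract.
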