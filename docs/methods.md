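# Methods

## Emotional profiling on the VAD model

The package treats each affective state as a point in a three-dimensional
space: valence (pleasant–unpleasant), arousal (stimulating–sedating) and
dominance (in control–controlled). Word norms supply per-lemma ratings on a
1–9 scale; `vad.rescale` maps them affinely to [0, 1] ((raw − 1)/8), and a
document's profile is the mean and standard deviation of the rescaled
values of its lexicon-matched lemma *tokens* (a lemma occurring k times
contributes k observations). Valence is kept scalar rather than split at
the midpoint into a polarity, so all three dimensions are comparable.

Assumptions and conventions:

- **Unmatched tokens are skipped, never imputed.** Norm lexicons cover only
  ~14k lemmas; imputing the scale midpoint would silently pull every
  document toward neutrality. Coverage (matched/total tokens) is always
  reported so low-coverage profiles can be discounted.
- **Token weighting.** Document and group ("term") averages weight by token
  occurrences. A mean-of-session-means alternative is available
  (`group_summary(..., weighting="mean_of_means")`) because published
  summary tables rarely state which convention they used; with roughly
  equal session lengths the two differ little.
- **SD convention.** Sample SD (ddof = 1) by default, population by flag —
  again because summary tables rarely say which was used. A
  single-observation document reports SD 0.
- **Bag-of-words.** Scoring is order-invariant by construction. Word norms
  are averages of rater responses and are blind to homonymy, negation and
  phrasing; profiles are lexical proxies, not utterance-level emotion.

A known bias: the longer a text, the closer its mean drifts to the
language-wide background mean. Sessions of roughly equal length make this
a shared offset rather than a confound.

## Decile word tiers

Per group, all discussion documents are concatenated; distinct matched
lemma *types* are ranked on one dimension's value and cut into ten tiers of
⌊n/10⌋ types (stable sort, so tied values resolve in lexicographic order
deterministically). The top and bottom tiers are reported with corpus token
frequencies (suitable for frequency-sized word clouds). If every type
shares one value the split is degenerate and raises rather than returning
an arbitrary partition. When two groups are compared, words present in both
groups' same tier are dropped (`exclude_common`) — most words carry some
positive valence, so the shared core otherwise swamps the group-specific
signal; a within-group top-vs-bottom exclusion (`exclude_within`) exists as
an alternative reading of that rule.

## Paragraph-vector embedding (PV-DBOW)

Each document d gets a trainable vector **d**; training maximizes, for
sampled target words w,

    log σ(u_w · d) + Σ_{k=1..K} log σ(−u_{n_k} · d)

with noise words n_k drawn from the unigram distribution raised to 0.75.
This is the distributed-bag-of-words paragraph-vector variant: the document
vector alone predicts its words. The "window" parameter is honoured as the
span around each document position from which the target word is sampled —
a discourse-span parameter rather than a word-order model. It defaults to
the group's rounded mean sentence length (measured on raw tokens before
stopword removal, since the window should reflect discourse span, not
filtered density); conversational sentences are long, so windows land
around 10–14.

Parameters (defaults): `dim` 100 (vector dimensionality), `window` from
sentence statistics, `epochs` 30 000 full passes (the stabilization point
for corpora of a dozen short documents; desk-scale tests use hundreds to a
few thousand), `negatives` 5, learning rate linear 0.025 → 0.0001, `min_count`
1 (the corpora are tiny; rare words are the signal, not noise).

Optimization is plain sequential SGD in corpus order, single-threaded, all
sampling from one seeded generator, inner loop JIT-compiled with numba —
two runs with the same config are bit-identical. The per-triple objective
and its analytic gradient are exposed (`triple_loss`, `triple_grads`) and
verified against central finite differences (max abs error < 1e-6 at
eps = 1e-6 in float64). Vectors are initialized uniformly in
±0.5/dim. The mean per-position loss of every epoch is recorded; on the
synthetic corpora it falls steeply over the first tenth of training.

Document similarity is raw cosine. A display map s → (s+1)/2 onto [0, 1]
is available for heat-map compatibility (0 = anti-aligned, 1 = identical)
but all statistics use raw cosine. One model is trained per group by
default (the window is a per-group quantity); a joint model over both
groups is available by flag. Inference of unseen documents is out of
scope — every document is in the training set.

## Inferential layer

- Pearson product-moment r with the two-sided p from the t transform
  (scipy), requiring n ≥ 3 and non-zero variance.
- Similarity–VAD correlations pool all sessions of both groups (12 in the
  study-shaped configuration); the emotion variable is the session-mean VAD
  level by default, with word-level SD (dispersion) selectable — both are
  defensible operationalizations of "emotional volatility".
- Independent-samples t-test: Student's pooled-variance form by default
  (the conventional choice at n of 6–9 per group), Welch by flag; sign
  convention is mean(first group) − mean(second group) with groups passed
  in a fixed order (MT, HT).
- Feedback tables (participant × item, 0–5 scale) get one t-test per item;
  raw p-values by default with items flagged at α = .05, and optional
  Benjamini–Hochberg adjustment, since dozens of items at α = .05 invite
  false positives. An item scored identically by everyone is reported as
  t = 0, p = 1 (no evidence of difference) rather than NaN.
- Non-significant results are never suppressed: the numeric p is always
  emitted with an `ns_at_0.05` flag.

## Synthetic-corpus generator

The generator emulates the statistical structure the analyses assume, with
study-shaped defaults: two groups (MT, HT), six analysed sessions each,
eight speakers in colour-code pseudonyms, 32 feedback items on a 0–5 scale
with 9 and 7 participants, Poisson sentence lengths with mean 12 tokens
(typical of discursive conversation), vocabulary 1000, 300-token sessions,
and per-group mean-VAD targets giving the second group slightly higher
valence/arousal and lower dominance.

Mechanics:

- **Lexicon**: lemmas `w0001…wN` with V/A/D drawn uniformly on [1, 9]
  (or Beta-shaped per dimension, since real valence norms are skewed).
- **Topics**: each session has a topic subvocabulary (default 80 types)
  sampled without replacement; the literary segment draws uniformly from
  it. Each discussion token is topical with probability `overlap`, else
  background. This vocabulary-partition structure keeps the recovery
  oracle analytic: higher overlap must yield higher text–discussion
  similarity.
- **Emotional register**: background draws are rejection-sampled with a
  Gaussian acceptance kernel (width `vad_noise`, default 0.1) in rescaled
  VAD space. The kernel centre is compensated for the topical fraction
  using the realised topic-subvocabulary mean, so the *document* mean hits
  the target irrespective of overlap; a 5000-token session recovers its
  valence target within ±0.02. At extreme overlap the background fraction
  cannot reach the target; the kernel centre is then clamped to the
  feasible edge and the ground-truth record flags `register_clipped`. A
  target farther than five kernel widths from every lexicon entry raises.
- **Feedback**: integer 0–5 scores around drifting item baselines;
  planted effects shift designated items' latent means in the second
  group before discretization.

Everything derives from one master seed (per-session generators are
spawned from (seed, group, session)), so corpora are bit-reproducible.

What the generator does *not* emulate: real word-frequency distributions
(no Zipf), syntax, discourse coherence, turn-taking dynamics, speaker
styles, or correlations between a word's VAD value and its topicality.
Passing recovery tests therefore shows the pipeline extracts the signals
it claims from data that contain them — not that real reading-group
transcripts contain such signals, nor how preprocessing choices interact
with real lexical statistics.

## Validation problem sizes

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen so the full suite completes in minutes on one CPU: overlap-recovery
at vocabulary 500, 12 sessions of 200 tokens, 50-dim vectors, 2000 epochs,
20 seeds (mean Spearman between planted overlap and recovered similarity
≥ 0.8; observed ≈ 0.97); end-to-end arousal-correlation recovery at
vocabulary 300, 150-token sessions, 32-dim vectors, 300 epochs, 100
replicates (negative r recovered in ≥ 95%; observed 100%); t-test
type-I-error calibration over 2000 null simulations (0.05 ± 0.01).

In the acceptance script's study-shaped run the groups differ in overlap
(0.7 vs 0.4) but share nearly equal arousal targets, so the pooled
similarity–arousal r there carries almost no planted signal and its sign
varies by seed — the realistic small-sample behaviour for n = 12; the
controlled recovery experiment above is the informative statistic.

## Numerical and degenerate-input choices

- Sigmoid and log-sigmoid are computed in the numerically stable split
  form; training raises on a non-finite epoch loss, naming the epoch.
- A document with no lexicon-matched token has no defined profile and
  raises; likewise volatility with fewer than 2 matched tokens, decile
  splits with fewer than 10 matched types, correlations with constant
  input, and t-tests with fewer than 2 observations per group.
- Transcript parsing: a speaker tag is a leading `[A-Z][A-Z0-9_-]*:` line;
  anything else continues the previous utterance. Bracketed stage
  directions (`[laughter]`) are preserved on disk and stripped during
  tokenization (a flag keeps them), so raw data is never destroyed.
- The bundled lemmatizer is a dictionary of irregular forms plus
  conservative suffix rules, iterated to a fixed point (hence idempotent);
  it trades linguistic accuracy for determinism and zero model downloads.
  spaCy can be plugged in where accuracy matters; results are
  preprocessing-sensitive, which is why run metadata records the stopword
  list and lexicon checksums alongside all hyperparameters and seeds.

## Known limitations

- Lexicon-based VAD is insensitive to negation, irony and homonymy.
- PV-DBOW on a dozen short documents is sensitive to hyperparameters and
  seed; similarities are comparable within a run, not across configs. The
  similarity scale is raw cosine; "0 means unrelated" holds only loosely
  for trained embeddings.
- The t-tests treat sessions and participants as independent units;
  repeated speakers across sessions violate this mildly (a mixed-effects
  model is out of scope).
- Exact reproduction of published tables from deposited study data
  requires the original transcripts and norms file plus their exact
  preprocessing (lemmatizer, stopword list), which is why the package
  exposes checksums and pluggable backends rather than claiming
  replication.
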