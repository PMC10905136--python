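# groupread

Quantitative analysis of group-reading (bibliotherapy) discussion
transcripts. Reading groups meet over a term, read a literary text aloud,
and discuss it; the transcripts of those discussions carry measurable
traces of the group's emotional and cognitive engagement. `groupread`
turns speaker-coded transcripts and the literary segments read in each
session into:

- **Emotional profiles** on the valence–arousal–dominance (VAD) model of
  affect, using word-norm lexicons (e.g. the ~14k-lemma Warriner norms,
  rated 1–9 and rescaled to [0, 1]): per-session and per-group means and
  dispersions of the rescaled norm values of all lexicon-matched word
  tokens, with coverage always reported.
- **Decile word tiers**: per group, the matched vocabulary is ranked on one
  VAD dimension and split into deciles; the top and bottom tiers (with
  corpus frequencies) show which words drive each group's emotional
  register. When two groups are compared, words appearing in both groups'
  same tier are excluded.
- **Text–discussion similarity** from an in-repo paragraph-vector
  (PV-DBOW) embedding trained with negative sampling: for target words *w*
  sampled around each position of document *D* with vector **d**,

      L = −log σ(u_w·d) − Σₖ log σ(−u_{n_k}·d),   n_k ~ unigram^0.75

  optimized by seeded, single-threaded SGD with linear learning-rate decay
  (bit-reproducible). Cosine similarity between a session's discussion
  vector and its text vector measures how "on topic" the discussion was;
  the context window defaults to the group's rounded mean sentence length.
- **Small-sample inference**: Pearson correlations between per-session
  similarity and per-session VAD, and independent-samples t-tests
  comparing the two groups' session VAD means and questionnaire feedback
  (0–5 scales), with numeric two-sided p-values always reported and
  optional Benjamini–Hochberg correction.
- **A seeded synthetic-corpus generator** producing norm lexicons,
  literary segments, multi-speaker transcripts with controllable topical
  overlap and emotional register, and feedback tables with planted
  effects — so the whole pipeline is testable end-to-end with known ground
  truth and no data downloads.

## Worked example

```bash
# generate a synthetic two-group corpus (6 sessions each; the MT group
# generated more "on topic" than HT: overlap 0.7 vs 0.4)
groupread simulate --seed 2 --out corpus

cat > run.yaml <<EOF
paths:
  transcripts: corpus/transcripts
  segments: corpus/segments
  lexicon: corpus/lexicon.csv
  feedback: corpus/feedback.csv
  out: out
embed: {dim: 50, epochs: 1500}
seed: 11
EOF

groupread report --config run.yaml
```

`out/` then contains the full bundle: `doc_profiles.csv`,
`group_term_summary.csv`, `group_session_summary.csv`, `tiers_*.csv`,
`similarity_matrix.csv`, `text_discussion_similarity.csv`,
`similarity_vad_correlation.csv`, `group_vad_ttests.csv`,
`feedback_ttests.csv` and a `run_metadata.json` (seeds, hyperparameters,
input checksums) from which the run is exactly reproducible. On this
corpus the text–discussion similarity table shows the planted contrast —
MT sessions average cosine 0.698 against their texts versus 0.543 for
HT — and `group_vad_ttests.csv` reports

```
dimension         t   df        p  mean_mt  mean_ht  ns_at_0.05
  valence -3.234666 10.0 0.008950 0.583342 0.612559       False
  arousal -0.811318 10.0 0.436068 0.381506 0.392505        True
dominance  4.014057 10.0 0.002462 0.599485 0.574833       False
```

i.e. the HT sessions' valence register sits above MT's and their dominance
below (sign convention: mean(MT) − mean(HT)), matching the generator's
per-group targets (valence 0.58 vs 0.616, dominance 0.62 vs 0.594).

The same pipeline runs on real data: transcripts as UTF-8 text with
speaker-coded utterances (`GOLD: I might agree,`), one literary segment
per session, and a Warriner-style norms CSV. Deposited spreadsheet data
can be converted with `groupread.convert_xlsx`.

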