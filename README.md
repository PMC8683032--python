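# bprtool

Model-based correction of pupillometry time series for blink-locked
pupillary responses.

## The problem

Every eye blink triggers a stereotyped pupillary response: a constriction
of roughly 0.1–0.3 mm that begins a few hundred milliseconds after the
blink and takes about 3 s to recover. Humans blink several times a minute,
and — crucially — not at random: blinks are suppressed while a stimulus is
on screen and concentrate at implicit task breakpoints such as the moment
after a response. Blink timing therefore couples to task structure and
cognitive state, and the blink-locked response (BPR) becomes a
*confounder* of event-related pupillometry, not just noise. Combined with
the convention of baselining each trial at its onset sample, it produces
spurious dips, inflations and condition differences.

`bprtool` is for researchers analysing continuous pupil recordings. It

* defines blink events and cleans peri-blink artifacts,
* fits a generative model of the blink-locked response per run,
* removes each blink's response individually (counterfactual correction),
* simulates confounded experiments with full ground truth, and
* quantifies what the correction buys in statistical power, against the
  common 3-s linear-interpolation practice.

## The model

Pupil traces are band-pass filtered (0.02–4 Hz) and analysed in 3-s
windows of 16 samples at 5 Hz. Blink-free windows `Y_free` and
blink-affected windows `Y_aff` (anchored at blink offsets) follow

```
g(Y_free; λ)              ~  MVN(μ_free,      Σ)
g(Y_aff − θ_j · h; λ)     ~  MVN(μ_affected,  Σ)
Σ_kl    =  σ² ρ^|k−l|                    (stationary AR(1))
h(x)    =  γ · f(x − t; α, β)            (gamma density, shape–scale)
```

where `g` is a shifted box-cox power transform, `Σ` models the temporal
autocorrelation of spontaneous pupil fluctuations, `h` is the subject's
blink-response kernel (γ < 0 encodes constriction; the kernel troughs at
`t + (α−1)β` seconds after the blink offset), and `θ_j` is a per-blink
gain — blink-to-blink amplitude variability is large (the top amplitude
quantile is several-fold the bottom one), so a single average kernel is
not enough. Fitting is staged maximum likelihood: λ (profile box-cox on
pooled blink-free values) → mean profiles → (σ, ρ) → (α, β, γ, t) with
multi-start → one bounded 1-D search per θ_j. Correction subtracts
`θ̂_j · ĥ` at the native sampling rate over each blink's 3-s footprint.

## Worked example

Simulate a two-minute fixation-style recording, preprocess, fit and
correct — via the CLI (the same steps are available as library calls:
`synthesize_trace`, `preprocess_trace`, `fit_bpr_model`, `subtract_bpr`):

```bash
bprtool simulate --preset fixation --duration 120 --rate 100 --seed 3 --out-dir sim
bprtool preprocess --trace sim/trace.tsv --rate 100 \
    --out-trace filt.tsv --out-blinks blinks.tsv
bprtool fit --trace filt.tsv --rate 100 --blinks blinks.tsv --out model.json
bprtool correct --trace filt.tsv --rate 100 --blinks blinks.tsv \
    --model model.json --method model --out corrected.tsv
bprtool evaluate --trace filt.tsv     --rate 100 --blinks blinks.tsv --out pre.json
bprtool evaluate --trace corrected.tsv --rate 100 --blinks blinks.tsv --out post.json
```

On this run the pipeline prints:

```
synthetic run (23 blinks) -> sim
23 blinks detected; filtered trace -> filt.tsv
model written to model.json
```

with fitted parameters `α = 4.90, β = 0.172 s, γ = −0.113 mm,
t = 0.260 s` (kernel trough ≈ 0.93 s after blink offset), noise
`σ = 0.078, ρ = 0.90`, and 23 per-blink amplitudes (mean 1.04, range
0.03–3.58 — the blink-to-blink spread the model exists to capture). The
`evaluate` reports show the Euclidean distance between the mean
blink-locked and mean blink-free 16-point profiles dropping from `0.341`
before correction to `0.103` after: the blink-locked average now looks
like blink-free background, which is exactly what a selective removal of
the blink response should achieve.

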