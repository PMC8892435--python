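# Methods

## The annotation model

AIF (all-ion-fragmentation) acquisition alternates a low-collision-energy
scan, which records intact ions (here called the MS1 channel), with a
high-energy scan that fragments everything co-eluting at that instant (the
AIF channel). Because there is no precursor isolation, a fragment's only
link to its parent is chromatographic: a true fragment's extracted ion
chromatogram (EIC) is an (approximately) scaled copy of the parent's
elution profile. `aifannot` exploits this with plain Pearson correlation:

- Every distinct AIF peak m/z within ±`rt_window` of the target feature is
  treated as a candidate channel (peaks across scans are grouped into
  channels by greedy nearest-centroid clustering at the EIC tolerance,
  seeded by the most intense peaks with an m/z tie-break — deterministic
  and independent of scan order).
- Each channel's AIF EIC is linearly interpolated onto the MS1 scan times
  (the two channels interleave in time, so their grids never coincide) and
  correlated with the feature's MS1 EIC.
- Channels with r strictly greater than θ form the pseudo-MS/MS spectrum.
  If none pass, or the feature has no MS1 signal, the raw AIF spectrum
  nearest the feature RT is substituted and flagged (`is_fallback`); a
  fallback changes how downstream matches are weighted (see scoring).

Correlation deconvolution cannot separate perfectly co-eluting compounds:
their fragments all correlate with either parent. This is accepted, not
patched — the library-matching stage resolves the ambiguity, because a
candidate is only rewarded for peaks matching *its own* expected fragments.

### Isotopologue correction

Fragment libraries contain monoisotopic masses only, while feature lists
from peak pickers routinely contain M+1…M+3 isotope peaks. Only carbon
isotopologues are considered: within an isotope envelope the EICs are
near-identical and, for small molecules, intensity decreases with k. The
walk starts at the feature m/z and repeatedly inspects the MS1 peak one
¹³C–¹²C spacing (1.00336 Th, tolerance 0.01 Th) below the current one; it
steps down only when that peak exists, correlates with the feature EIC at
r > `r_iso`, and is *more intense* (EIC apex) than the current peak. The
number of steps is the offset k (capped at `max_k` = 5) and the corrected
monoisotopic m/z is snapped to the observed peak centroid. The procedure is
idempotent: re-running it on the corrected m/z returns offset 0.

### Candidate selection and matching

Selection is two-pass: parent m/z within `ppm_tol` of the corrected
monoisotopic m/z; only when that pass is empty, a search through library
fragment m/z values (the feature may be an in-source fragment, which AIF
workflows must expect in MS1). For in-source-fragment candidates the ppm
error E is computed against the matched fragment m/z — the only
self-consistent reference, since the feature is not the parent.

Matching is per library ion (parent first, then fragments): nearest
pseudo-MS/MS peak within `frag_tol` wins (set P); ions unmatched there —
or all ions when the pseudo spectrum is a fallback — are searched in the
raw AIF spectrum (set A). Each library ion is matched at most once, with
pseudo-MS/MS precedence, so P ∩ A = ∅; one observed peak may serve several
library ions (shared fragments are real, e.g. head groups).

### Scoring

    S = w_mz · S_mz + w_ma · S_ma
    S_mz = min(1/E, 1)                       (E in ppm; S_mz = 1 at E = 0)
    S_ma = Σ_{ion∈P} s_ion + (1/2) Σ_{ion∈A} s_ion

Occurrence scores s weight each library ion by how reliably it is observed;
they substitute for the relative intensities an experimental MS/MS library
would carry, and their numeric scale is left to library authors (defaults
when absent: parent 1.0, fragment 0.5 — parent presence is the strongest
single piece of evidence). AIF-only matches are down-weighted by the factor
2 because any co-eluting compound can contribute them. The parent ion's own
occurrence score counts toward S_ma when the parent is found among the
observed peaks (configurable via `ScoringConfig.count_parent_evidence`);
S_ma is deliberately *not* normalised by the candidate's total possible
score — the separate `fraction` output reports coverage instead. Ties in S
are broken by lower E, then more pseudo-MS/MS matches, then name — a total,
deterministic order.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| θ (`theta`) | 0.8 | Pearson-r threshold for pseudo-MS/MS membership (strict >); usual working range 0.7–0.8 |
| `ppm_tol` | 25 ppm | candidate-selection tolerance, typical for Q-ToF mass accuracy |
| `frag_tol` | 0.01 Th | fragment/EIC m/z tolerance, Q-ToF peak width scale |
| `w_mz` | 0.5 | weight of the mass-accuracy subscore; `w_ma = 1 − w_mz` |
| `rt_window` | ±10 s | correlation window half-width; covers a UPLC peak (σ ≈ 3 s) with margin while keeping correlations local |
| `min_points` | 5 | minimum EIC points for a defined correlation |
| `r_iso` | 0.8 | correlation threshold for isotope evidence (exposed separately from θ) |
| `max_k` | 5 | deepest isotopologue considered |
| `aif_downweight` | 2 | divisor for AIF-only match evidence |
| `k_max` | 5 | rank cutoff treated as correct in evaluation |

RT is seconds everywhere internally; mzML scan times declared in minutes
are converted at parse time. Channel splitting (MS1 vs AIF) is configurable
— `mslevel` (default), `ce:<threshold>` on collision energy, or `alternate`
parity — because converters encode the high-energy function inconsistently.

## Evaluation arithmetic

A feature is *correct* at the smallest rank r ≤ k_max whose candidate
matches the reference label (case-insensitive, whitespace-trimmed names;
adducts compared after bracket stripping when both sides supply one),
*incorrect* if candidates exist but none match, *unannotated* otherwise.

    precision = 100 · correct / (correct + incorrect)
    recall    = 100 · correct / (correct + unannotated)

Percentages are rounded half-up to one decimal. Note the recall denominator
excludes incorrectly annotated features — this is the definition consistent
with the published count tables this implementation is checked against,
although it differs from the conventional TP/(TP+FN). Two published
precision cells (negative-mode lipid rows) disagree with their own printed
counts by ~0.1–0.2 points; they are treated as source-side rounding
inconsistencies and only the recall of those rows is asserted.

## The synthetic-data generator

`simulate_run` emulates exactly the structure the workflow assumes:

- one Gaussian elution profile exp(−(t−rt_apex)²/2σ²) shared by a
  compound's parent and all its fragments (σ default 3 s — a typical UPLC
  peak width);
- MS1 scans carry the parent with a binomial(n_carbons, 0.0107) ¹³C
  envelope spaced 1.00336 Th, plus declared in-source fragments; AIF scans
  carry the parent attenuated to 0.3 plus all fragments;
- acquisition alternates MS1/AIF within a 0.5 s cycle over 600 s;
- noise: mean-one multiplicative log-normal factors at a stated CV on true
  peaks, plus Poisson-count spurious peaks at uniform m/z with exponential
  intensities; everything drawn from one seeded generator (byte-identical
  reruns);
- peaks below 1 count are dropped (detector floor), truncating Gaussian
  tails and tiny isotope peaks.

Canned bundles: `clean` (25 well-separated compounds, 3 fragments each, no
noise), `co-eluting` (five pairs sharing an RT apex and one nonspecific
fragment at 184.0733, the phosphocholine head-group scenario), `noisy`
(clean + CV 0.2 + 50 spurious peaks/scan).

What the simulator does **not** model — and what a green end-to-end test
therefore does not establish robustness against: chromatographic tailing or
fronting (profiles are exactly Gaussian, so correlations are optimistically
high), mass-calibration drift, detector saturation, ion suppression,
charge states > 1, multimers, and realistic spectral congestion where many
hundreds of compounds elute per minute. Recovery rates on these bundles are
upper bounds, not predictions for instrument data.

## Numerical choices

- Pearson r is computed on centred vectors with an explicit zero-variance
  guard: a constant EIC yields *undefined* (None), which every caller
  treats as below threshold, never as 0 or 1. Values are clamped to
  [−1, 1] against rounding.
- "Greater than θ" is strict, so θ = 1.0 rejects even perfectly correlated
  noiseless channels (floating-point interpolation keeps r fractionally
  below 1) and exercises the fallback path.
- E = 0 gives S_mz = 1 (the limit of the bound, not a division).
- mzML binary data are written 64-bit little-endian, zlib-compressed by
  default; the reader also accepts 32-bit floats and uncompressed arrays.
- `spectrum_near` merges the 3 nearest scans with intensity-weighted
  centroids at 0.01 Th to suppress single-scan dropouts.
- Degenerate inputs: empty RT windows raise; an all-zero feature EIC falls
  back with a warning; a run whose split rule leaves one channel empty is
  rejected as "not an AIF run".

## Known limitations

- Only singly charged, single-molecule adducts: multimers ([2M+X]) and
  multiply charged species are out of scope and will be mis- or
  un-annotated.
- Only carbon isotopologues are corrected; S/Cl isotope patterns are not
  recognised.
- Profile-mode mzML receives only naive local-maximum centroiding; heavily
  overlapping profile peaks should be centroided upstream.
- The co-elution ambiguity is resolved only as well as the libraries
  discriminate: two candidates sharing all observed fragments tie up to E
  and rank by mass error alone.
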