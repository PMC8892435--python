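# aifannot

Automated annotation of untargeted **all-ion-fragmentation (AIF)** LC–MS
features — the acquisition mode also marketed as MSᴱ, MS/MSᴬᴸᴸ or bbCID, in
which low- and high-collision-energy scans alternate with no precursor
isolation.

Untargeted metabolomics and lipidomics experiments yield thousands of
features (m/z–RT pairs) that mix adducts, isotopologues and in-source
fragments. AIF acquisition records fragmentation for *everything* at once,
so before any library can be searched the parent–fragment relationships
must be reconstructed. `aifannot` targets the analyst who already has a
feature list (from XCMS, MZmine, …) and wants automated, ranked candidate
annotations for a chosen subset of features, rather than an untargeted
annotation of the whole run.

## What it does

For each target feature the workflow:

1. extracts the feature's MS1 EIC and **all** AIF ion chromatograms in the
   same RT window, and keeps AIF channels whose Pearson correlation *r* with
   the feature EIC exceeds a threshold θ (default 0.8) — these form the
   **pseudo-MS/MS spectrum**; if none pass, the raw AIF spectrum at the
   feature RT is substituted;
2. determines the **carbon isotopologue** (M+k): it walks down from the
   feature m/z in steps of 1.00336 Th while a correlated (*r* > 0.8), more
   intense MS1 peak exists, yielding the monoisotopic m/z;
3. selects **library candidates** whose parent m/z lies within 25 ppm of the
   monoisotopic m/z (falling back to a fragment-m/z search for in-source
   fragments);
4. matches each candidate's parent and fragment m/z values to the
   pseudo-MS/MS peaks at 0.01 Th, searching leftover ions in the raw AIF
   spectrum (this recovers nonspecific fragments shared by co-eluting
   compounds, e.g. phospholipid head groups);
5. scores and **ranks** candidates:

   S = w_mz · min(1/E, 1) + w_ma · ( Σ_{i∈P} s_i + ½ Σ_{i∈A} s_i )

   where *E* is the ppm error of the parent match, *P*/*A* are the ion sets
   matched in the pseudo-MS/MS / AIF spectra, *s_i* is each library ion's
   **occurrence score** (a curated weight for how often that ion is
   observed), and w_mz = 1 − w_ma (default 0.5/0.5).

Libraries are flat CSV files (one per metabolite class × adduct) holding
parent and fragment m/z values with occurrence scores; they can be imported
from MSP/txt spectral files or generated for lipid classes from
chain-composition templates. Precision/recall evaluation against reference
annotations, with "correct" meaning found in ranks 1–k (default 5), is
built in.

A fully seeded **synthetic AIF-run simulator** (Gaussian co-elution,
binomial ¹³C envelopes, in-source fragments, log-normal intensity noise,
spurious peaks) generates mzML runs with truth tables so every stage is
testable without instrument data.

## Worked example

```python
from aifannot import Feature, ScoringConfig, annotate_feature, make_test_suite

sim = make_test_suite("clean", seed=7)            # 25 compounds, no noise
t = sim.truth_parents()[3]                        # a known parent feature
feat = Feature(mz=t.mz + 1.00336, rt=t.rt, id="F004.M1")  # its M+1 isotopologue
res = annotate_feature(sim.run, feat, sim.library, ScoringConfig())
```

prints (via the fields of `res`):

```
feature: F004.M1 m/z 376.4355  RT 100 s
isotopologue: M+1, corrected monoisotopic m/z 375.4321
pseudo-MS/MS: 7 peaks (fallback=False)
rank 1: CPD04 [M+H]+  E=0.00 ppm  |P|=4 |A|=0  S_mz=1.000 S_ma=2.500 S=1.750
```

The feature was injected on the M+1 isotope peak; the walk-down recovers
offset 1 and the monoisotopic m/z 375.4321, which selects the true compound
at 0.00 ppm. All four library ions (parent + 3 fragments) are found in the
pseudo-MS/MS spectrum, so S_ma = 1.0 + 3·0.5 = 2.5 and
S = 0.5·1 + 0.5·2.5 = 1.75.

## Command line

```bash
aifannot simulate --spec sim.json --out simout          # synthetic run + truth + library
aifannot annotate --features features.csv --data run.mzML \
                  --library libdir --polarity positive --out annout
aifannot evaluate --results annout/annotations_all.csv \
                  --reference reference.csv --kmax 5
```

`annotate` accepts mzML raw data or precomputed pseudo-MS/MS spectra
(`.msp`), writes per-feature ranked candidate CSVs, a rank-1 summary, an
`annotations_all.csv` for evaluation, optional per-feature PDFs, and echoes
the resolved configuration to `run_config.json`.

## Acceptance script

`scripts/acceptance.py` re-runs the package's primary end-to-end
computation from scratch: it simulates the clean (25 compounds, noiseless)
and noisy (CV 0.2, 50 spurious peaks/scan) bundles with the given seed,
annotates every truth parent, evaluates rank-1 and rank-1–5 recovery, and
writes the results JSON.

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
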