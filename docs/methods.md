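# Methods

## Model

The pipeline treats candidate-gene prioritization as weighted vote
counting. A curated database assigns each study to a species group
(human / songbird / other animal), a study group (gene-mapping vs other —
the two sample-size scaling pools), one or more subphenotype classes
(listening, ability, practice), a phenotype-precision flag and a sample
size. Studies cast votes through evidence layers: one layer per evidence
kind (association, linkage, expression, other molecular) per independent
dataset, so a study reporting association and linkage results contributes
two layers and a reanalysis of three transcriptome datasets contributes
three. Layer *i* has weight `w_i` and a detected-molecule set; the
molecule-level score is

    CE_g = Σ_i w_i e_gi / Σ_i w_i ,   e_gi ∈ {0, 1}.

The score is a weighted mean, so it is invariant to rescaling all weights,
bounded in [0, 1], equals 1 only for a molecule detected in every analyzed
layer, and reduces to the plain vote fraction under uniform weights. It
uses no per-study p-values or effect sizes — deliberately, since the
evidence base mixes designs for which those are unavailable or
incomparable.

### Custom scores

`w_i` is the product of three factors, each spanning [0.8, 1]:
phenotype precision (1.0 precise / 0.8 related), homology conversion
(1.0 human / 0.8 other species), and sample size (linear from 0.8 at the
pool minimum to 1.0 at the pool maximum, pools = gene-mapping vs other
studies); a linkage layer whose study also contributed an association
layer is additionally multiplied by 0.9, reflecting the partial redundancy
of the two gene-mapping signals from one cohort. Weights therefore lie in
[0.8³·0.9, 1] = [0.4608, 1], and in [0.512, 1] when no linkage pairing
occurs. The factors penalize layers whose evidence is more likely to be
diluted (vague phenotype, cross-species homology, small cohorts) without
ever zeroing a layer out.

Two conventions the weighting scheme leaves open were fixed as follows:
a scaling pool whose sizes are all equal (including a singleton pool)
scores 1.0 — a single-study pool carries no information to penalize; a
missing sample size takes the floor 0.8 with a logged warning —
conservative, and visible in the audit table. Factors are exact decimals
multiplied in double precision; scores are rounded (3 decimals) only at
reporting time.

### Region-to-gene mapping

Association markers become ±500 kb windows (default `flank_bp = 500000`);
linkage peaks reported only in genetic-map units are converted at exactly
1 cM = 1 Mb around the peak. The half-width used when only a peak position
is reported is a visible configuration parameter
(`linkage_half_width_cm`, default 10 cM) — published reports vary in how
much of the peak they delimit, so no single default can reproduce every
curated region. Coordinates are 1-based inclusive (GFF3/Ensembl
convention; BED input is converted on read), windows are clamped to
chromosome bounds, and a gene is extracted if it overlaps the window by at
least one base pair, strand ignored. A window containing no gene drops its
marker with a log entry rather than failing — gene deserts are an expected
outcome. The interval index is an `intervaltree`; tests hold it to an
exhaustive-scan oracle.

### Homology translation

Cross-species translation is a user-supplied many-to-many table; when a
non-human gene has several human homologs, **all** are kept (expansion
before deduplication). Identifiers with no mapping are dropped and counted
per layer; a layer whose whole detected set is unmapped is dropped with a
warning. Proteins are expected to be mapped to their encoding genes
through the same table; hormones and other biomarkers pass through
untranslated via the controlled biomarker vocabulary (canonical
lower-case, matched case-insensitively; genes are canonical upper-case).

### Ranking, ties, and the top set

Ranking is score-descending with deterministic tie-breaks: raw detection
count descending, then identifier ascending. The top set is the first
`ceil((1 − q)·N)` molecules with q = 0.995 by default — a count-based
rule rather than an interpolated quantile threshold, because the score
distribution is heavily tied at the bottom and a value threshold would be
tie-sensitive (at N = 7895 this rule keeps exactly 40). Subphenotype
rankings restrict to the layers of studies carrying the class, recompute
the weight denominator over that subset only, and drop molecules with no
subset support; subset scores are comparable within, not across, strata.
A small epsilon guards the `ceil` against float noise so exact fractions
like 0.005·200 = 1 do not round up.

### Enrichment and networks

Over-representation of the top set in a gene set is the one-sided
hypergeometric tail P(X ≥ k) (scipy `hypergeom.sf`), with the universe
defaulting to all molecules in the loaded database — the frame in which
the vote counting operated — rather than the genome. Raw p-values are
primary; a Benjamini–Hochberg column is optional and off by default.

The interaction-network builder reimplements the published growth sketch:
the seed is the focus (top-set) molecule participating in the most
triangles of the interaction graph (ties: degree, then name); growth
repeatedly adds the neighbour with the most edges into the current
network, preferring focus molecules among equally connected candidates,
until the size cap (35 by default) or until nothing connects; used nodes
are removed before the next seed, so networks are node-disjoint. The
commercial tool that inspired this procedure does not publish its
candidate scoring, so beyond the triangle-count seeding this greedy rule
is this package's own documented choice, not a claim of equivalence.
Focus molecules with no remaining interactions do not form singleton
networks.

## Synthetic data

The generator emulates the statistical shape of the curated literature
database: 35 human / 55 songbird / 15 other-animal studies by default;
gene-mapping (DNA) studies only in the human group (fraction 10/35), about
half of them reporting linkage alongside association; songbird studies
RNA-dominated; per-species subphenotype-class probabilities set to the
database's marginal composition. Sample sizes are uniform on 100–1000 for
gene-mapping studies and 6–50 for other studies — genome-wide human
cohorts versus small expression/animal experiments. Detection is
independent Bernoulli per (layer, molecule): planted signal molecules are
detected with `p_signal` (default 0.3) and background molecules with
`p_noise` (default 0.01) in every layer. Non-human layers emit
species-native identifiers resolvable through a generated homolog table in
which 10% of native genes are deliberately unmappable and 5% carry a
second (erroneous) human homolog. All randomness flows from a single seed;
generated files are byte-identical across runs.

What the generator does **not** model: correlation between layers
(publication bias, shared cohorts), linkage disequilibrium or realistic
region structure, expression dynamics, and any dependence of detection on
effect size. Independence across layers is exactly the null the vote count
assumes, so the benchmark demonstrates correct mechanics and statistical
behaviour of the pipeline — not that real literature satisfies those
assumptions.

`recovery_experiment` runs generate → translate → weight → score → rank
per replicate and reports the fraction of planted molecules inside the
top-K (K = number planted), with SD and a normal-approximation 95% CI
across replicates, plus mean ranks of planted vs background molecules (a
planted molecule missing from the ranking counts at rank = universe
size). At the default conditions (≈112 layers, 8000 molecules, 40
planted) recovery is ≈0.98: the deliberate homolog-table errors let an
occasional background symbol inherit a planted native gene's detections
and displace it — a realistic failure mode, retained on purpose.

## Numerical and interface choices

* Scores are computed vectorized (`w @ E / Σw`) in float64; tests pin them
  to a per-molecule loop oracle at 1e-12.
* All tabular IO is TSV with fixed column orders; scores print at 3
  decimals, weights at 6; reruns are byte-identical.
* Loader strictness: duplicate study ids, detections referencing unknown
  studies or undeclared evidence kinds, and declared kinds with no
  detections are hard errors; a missing `dataset_id` column defaults to a
  single dataset.
* The benchmark and tests use scaled problem sizes (hundreds of molecules
  for unit fixtures, the full 8000-molecule universe for the recovery
  benchmark at 50 replicates) chosen to exercise every code path while
  keeping the suite fast.

## Limitations

* The ranking has no uncertainty quantification (no bootstrap on ranks,
  no combined p-values) — the method is a prioritization heuristic, and
  the package keeps it as such.
* The enrichment stage ships no gene-set or interaction content; results
  depend entirely on the user-supplied GMT/edge inputs.
* Curation itself — literature search, inclusion thresholds, extraction
  of per-study results — is out of scope; the package starts from the
  tabulated database.
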