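# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical conventions.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Differential quantification model

Each phosphopeptide *i* quantified by enrichment method *m* carries a
heavy/light SILAC ratio; heavy is the wild type and light the phosphatase
deletion, so log₂(H/L) < 0 indicates hyperphosphorylation in the mutant.
Scan-level ratios are combined by a weighted mean on the log₂ scale.
Within each method the log₂ ratios are centred on their median, which
assumes most peptides are unchanged — reasonable when a single regulatory
subunit is deleted, questionable for perturbations with proteome-wide
effects.

Cross-method aggregation averages per-method H/L values arithmetically
(duplicates within a method are first averaged on the log₂ scale).  The
coefficient of variation is the sample standard deviation (n − 1) over the
mean **on the raw H/L scale**, because the filter cascade's companion rule
("every method ratio below 0.75") is stated on that scale.  The cascade
keeps a peptide when

1. CV < 0.40, or
2. the peptide was seen in a single method (no CV), or
3. CV ≥ 0.40 but every per-method H/L < 0.75,

recording which branch applied.  Classification uses the cross-method mean
with exclusive boundaries: hyper below 0.75 (log₂ ≈ −0.42), hypo above
1.3.

### Significance

For peptides quantified in at least two methods, significance is a
two-tailed one-sample Student *t*-test of the method-level log₂ ratios
against 0.  With at most three method-level values this is the only
contrast available; its df (1 or 2) makes it weak for two-method peptides,
which is a property of the design, not of the implementation.  Raw
*p* < 0.05 defines the significant set; Benjamini–Hochberg adjusted values
are emitted as an extra column for transparency but do not drive the call.
Zero-variance samples are not errors: *p* is forced to 0 (non-zero mean)
or 1 (zero mean) with a `degenerate_p` flag, so a noiseless limit remains
analysable.

Protein abundance from the non-enriched run is aggregated per protein as
the median peptide H/L; a protein is `unchanged` at H/L ≥ 0.8 and
`reduced` below.  The flag annotates, it never removes a peptide.

## Motif extraction

Phosphosites are represented by 13-residue windows centred on the site
('-' pads past termini; padded positions are excluded from all frequency
denominators).  Serine- and threonine-centred analyses run separately.
The background is every S (or T) of the reference proteome, windowed the
same way.

Extraction is greedy and iterative: at each step, for every signed offset
≠ 0 and residue, compute the binomial tail P(X ≥ k) with k the foreground
count, n the current foreground size and p the residue's background
frequency at that offset; select the smallest p (ties: larger k, then
smaller signed offset, then alphabetical residue) if p < `p_threshold` and
k ≥ `min_occurrence`; restrict both sets to matching windows and repeat.
When no pair qualifies, the accumulated mask is emitted as a motif — score
Σ −log₁₀ p over its steps, fold increase (fg match rate)/(bg match rate)
relative to the sets at the start of that motif's round — its matching
windows are removed, and extraction restarts.  Selected elements are
single residues; degenerate classes (e.g. D/E) are never merged.

Defaults `min_occurrence = 5` and `p_threshold = 1e-5` are calibrated for
foregrounds of tens of sites rather than thousands: with 76 sites, a real
proline-directed threonine motif carried by 6 of 11 threonine windows has
a binomial tail of a few 10⁻⁶ against a ~4.4% proline background, so the
classic web-tool thresholds (20 occurrences, 10⁻⁶) would discard true
consensus motifs at this scale.  Both are configurable.

Kinase-consensus annotation is pure pattern matching on the window:
Pro-directed (+1 P), GSK3 priming (+4 S/T), polo-type (−2 D/E/N), CK2
(+3 D/E), CK1 acidic-primed (−1 or −2 D/E).  The phospho-primed CK1/GSK3
variants require phospho-context at neighbouring sites and are not
evaluable from a single window, so they are not scored.

## Term enrichment and hubs

Enrichment uses the DAVID conventions.  For a term with `count` foreground
hits, `list_total` annotated foreground genes, `pop_hits` background hits
and `pop_total` annotated background genes: fold enrichment is
(count/list_total)/(pop_hits/pop_total); the p-value is the one-tailed
Fisher tail, by default in the EASE variant that decrements the foreground
count by one (equivalently P(X ≥ count − 1) under the hypergeometric
null), which penalizes terms supported by very few genes.  The background
defaults to all genes carrying any annotation; an explicit background
overrides it.  Gene symbols are upper-cased before matching.  BH
adjustment runs over all tested terms.  Kappa-statistic term clustering is
not reimplemented: cluster membership is an input grouping and only the
enrichment score, −log₁₀ of the geometric mean of the group's p-values, is
computed (groups above 1.5 count as enriched).  Hub analysis counts
degrees on the deduplicated undirected edge list (self-loops dropped); a
hub has degree strictly greater than the threshold (default 7).

## Docking post-processing

Poses are two-chain PDB files; atom radii come from a ProtOr-style
per-element table shipped as package data.  Superposition is a
least-squares rigid-body fit (Kabsch via SVD with a determinant correction
to exclude reflections); the test suite checks its RMSD against an
independent quaternion-eigenvalue implementation to 10⁻⁸.  The catalytic
filter keeps poses whose specified ligand/receptor atoms (default CA–CA,
residue-centroid fallback available) are within 10 Å **inclusive**, while
interface contacts use a **strict** < 5 Å any-atom criterion — the two
cutoffs follow the conventions of their respective sources.  Pose
similarity is the fraction of common contacts symmetrized conservatively
as min(|a∩b|/|a|, |a∩b|/|b|); two empty fingerprints are identical, empty
versus non-empty is 0.  Clustering is leader-style: repeatedly take the
unassigned pose with the most unassigned neighbours at similarity ≥ 0.75
(ties: lowest index) and form a cluster from it and those neighbours —
deterministic, every pose assigned exactly once.

Per-residue interface propensity over an ensemble of N poses is
log₂((count + 1)/(N·f̄ + 1)) with f̄ the mean interface frequency over
residues seen at least once — a pseudocount-smoothed log₂ enrichment over
the average interface residue, chosen so that a residue present in every
pose of a uniform ensemble scores exactly 0 and absent residues get a
finite floor.  The raw log₂ frequency is emitted alongside; the
normalization is a package choice since "log₂-scaled propensity" admits
several conventions.

SASA is Shrake–Rupley (probe 1.4 Å, 960 sphere points by default); the
sphere-point evaluation is delegated to biotite with this package's radius
table, and per-residue summation plus normalization are done here.
Relative accessibility divides by per-residue-type reference maxima
(theoretical Gly-X-Gly values); the main-chain reference is a single
extended-backbone constant (38 Å²) and the side-chain reference is the
total minus that constant (floored) — an approximation adequate for the
≥ 15% accessibility threshold, not for quantitative per-atom work.
Restraint selection requires both the distance criterion (any atom within
10 Å of any seed-residue atom) and accessibility of main **or** side chain
≥ 15%.

## The synthetic generator

`SimulationConfig` defaults are the reference study conditions: 500
phosphopeptides from a 200-protein yeast-composition proteome, 10% planted
hyperphosphorylated with log₂ effect −1.0, per-method Gaussian log₂ noise
0.2, three methods, 15.8% of proteins with reduced abundance (H/L ≈ 0.6),
planted +1-proline motif at 40% of eligible hyper serine sites (residual
background prolines at the planted offset are mutated away so the planted
fraction is exact), one planted annotation term (foreground inclusion 0.6
vs background 0.05) and one planted hub (degree 10).  `method_dropout`
defaults to 0 because the recovery conditions are stated for peptides
quantified in all three methods; a power analysis of the one-sample
*t*-test shows two-method peptides (df = 1) have ≈ 0.4 power at these
settings, so any appreciable dropout makes 90% sensitivity unreachable by
design, not by implementation.  Dropout is exercised explicitly in tests.

Peptides are tryptic-like (cleave after K/R except before P, lengths
7–35, ≥ 1 S/T).  Random streams are drawn per output family (proteome,
peptides, ratios, dropout, annotation, poses) from the master seed, so
regeneration is byte-identical and enlarging one family does not perturb
another.

The toy pose generator builds a 24-residue ring receptor and a rigid
6-residue ligand placed at family-specific anchor angles, with the
near-site family putting the ligand's phosphosite proxy 4.2 Å from the
catalytic residue; per-pose jitter (default sd 0.1 Å) is small relative to
the 0.8 Å margin to the 5 Å contact cutoff and the 5.8 Å margin to the
10 Å filter, so planted memberships cannot flip.

**What the generator does not emulate:** spectra, retention times,
enrichment-chemistry biases (dropout is independent per method, real
enrichment methods select correlated peptide classes), missed cleavages,
multiply-phosphorylated isoform interference, protein inference ambiguity,
and real docking energetics (toy poses have single-contact interfaces).
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated noise model, not robustness to every artefact
of real MS or docking data.

### Study-scale stand-ins

The deposited supplementary peptide tables of the reference dataset are
not shipped.  Two generators construct synthetic stand-ins whose ground
truth is planted to the study's printed marginal counts so the same code
paths can be exercised at scale: (a) a significant-set stand-in — 62
peptides carrying 76 sites (65 S / 11 T, 39 with +1 proline, of which 33
serine and 6 threonine), hosted in synthetic proteins with deterministic
motif-free flanking sequence; and (b) a cascade stand-in — 4,467
phosphopeptides with 1,260 planted hyper across exactly 628 proteins, 62
planted three-method significant hyper and 27 significant hypo, with
per-group ratio patterns whose margins to every threshold (0.75, 1.3, CV
0.40, t-critical values) are ≥ 4 standard deviations of the observation
jitter (sd 0.03), so a correct pipeline recovers the planted counts
exactly and any deviation indicates a defect.  These stand-ins validate
the pipeline against known truth; they cannot validate the upstream
identifications of the original data.

## Problem sizes and runtime

The default test suite runs ~160 tests in under a minute on one core:
exhaustive Fisher-tail enumeration covers all margins to N = 40 plus 150
random tables to N = 200 against an exact rational-arithmetic oracle;
binomial tails are checked to n = 500 at 10⁻¹²; parameter recovery
averages 20 independent 500-peptide screens; the cascade stand-in runs at
its full 4,467-peptide scale.  `scripts/acceptance.py` repeats the same
computations in ~15 s.

## Known limitations

- Whether the original analysis tested raw or normalized ratios, and which
  contrast its *t*-test used, is not documented upstream; one-sample on
  normalized method-level ratios is assumed and recorded here.
- Motif extraction results are sensitive to `p_threshold`/`min_occurrence`
  for foregrounds under ~100 sites; defaults are justified above but are
  choices.
- The EASE-vs-plain-Fisher ambiguity of annotation tools is resolved by
  emitting both (EASE is the default p).
- Single-window kinase annotation cannot see phospho-primed consensus
  chains spanning multiple sites.
- The SASA main/side-chain reference split is approximate (constant
  backbone reference).
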