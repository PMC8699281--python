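# Methods

## The model

`ms2mol` treats small-molecule identification from positive-mode ESI
tandem mass spectra as sequence-to-sequence translation.  The source
sentence is a list of m/z peaks, the target sentence a SMILES string.
Three components make this work:

1. **A forward fragmenter** that turns structures into theoretical
   protonated fragment spectra, providing unlimited paired training data.
2. **An encoder–decoder transformer** that learns the inverse map from
   binned peak lists to SMILES.
3. **A post-processing stack** — formula filtering against the exact
   precursor mass, round-trip spectral ranking, and fingerprint
   similarity — that turns raw samples from the decoder into a vetted,
   ordered candidate list.

The design is deliberately rule-light: the fragmenter encodes only bond
topology, and the network is given no valence rules, isotope patterns or
rearrangement chemistry.  Whatever regularities exist between fragment
masses and structure must be learned from data.

## In silico fragmentation

A molecule is represented as its heavy-atom graph; each atom keeps the
hydrogen count it has in the parent structure.  Eligible bonds are
single, non-aromatic bonds between heavy atoms.  Breaking a bridge bond
yields two fragments (the connected components); breaking a ring bond
yields one ring-opened fragment with the same atoms.  Both kinds of
break consume one unit of recursion depth.  The process recurses
breadth-first on every fragment until `max_depth` (default 3) or until a
fragment falls below `min_fragment_mass` (default 50 Da; set to 0 in the
test fixtures so that even 5-atom molecules fragment richly), at which
point the fragment is discarded and not recursed.  Each adduct shift
(default: protonation, +1.00727646 Da) is added to each surviving
fragment's neutral monoisotopic mass; m/z values are deduplicated at 5
decimals and sorted; the precursor ion is always reported.

Hydrogen bookkeeping is homolytic and frozen: no ±H transfer occurs on
cleavage.  This deliberately misses rearrangement fragments; it is the
price of a rule that is exactly reproducible and cheap enough to run
millions of times.

Duplicate suppression during recursion uses the state key
(atom set, set of already-broken ring bonds inside that atom set).  Two
states with identical atoms but different broken ring bonds have
different futures — the ring-opened variant can no longer break that
bond but exposes the rest of the ring — so keying on the atom set alone
could drop peaks.  With this key the output provably equals exhaustive
enumeration over all break sequences, which the test suite checks
against an independent brute-force enumerator on all fixtures with ≤ 8
heavy atoms at depths 1–2.

## Encoding

Peaks are restricted to m/z < 500 Da and binned at 0.01 Da:
`bin = floor(m/z × 100)`, 50,000 bins.  Truncation (not rounding) is
used — the bin is the integer part of the scaled mass — with a 1e-7
epsilon absorbing binary floating-point representation error.  A 5 ppm
instrument at 500 Da is accurate to 0.0025 Da, a quarter of a bin, so
binning dominates neither.  Inputs are the sorted, deduplicated bin
indices, at most 100 of them.  Intensities never enter the encoding or
the cosine score; they are used only to order peaks in the top-k
protocol, because relative abundances depend on collision energy while
peak presence does not.

The SMILES vocabulary is frozen at 69 tokens: `<sos>`, `<eos>`, `<unk>`,
`<pad>` at ids 0–3 plus 65 content symbols.  Two-letter element symbols
(Cl, Br outside brackets; any two-letter symbol inside brackets) are
single tokens; bracket expressions otherwise tokenize character-wise, so
detokenization is plain concatenation and round-trips exactly.  The
content set covers the organic subset, aromatic atoms, ring digits,
structural punctuation and a reserve of bracket-only element symbols for
library data; it ships as a versioned artifact so the size-69 contract
is testable.

## Dataset construction

Admission rules, applied in order: protonated-precursor m/z ≤ 500,
canonical SMILES ≤ 99 characters, ≤ 100 peaks, global duplicate removal
on canonical SMILES.  Canonicalization strips stereochemistry and
isotope labels — exact masses cannot distinguish stereoisomers, so the
model should not be asked to.

Each admitted molecule is fragmented at depths 1, 2 and 3 and
contributes one sample per depth (3× augmentation).  Shallow spectra
emulate the strong, trustworthy peaks of a measured spectrum, deep ones
the noisy tail; presenting all three teaches the model to anchor on the
informative peaks.  A depth's sample is dropped individually when its
binned peak list exceeds 100.

The train/validation split operates on molecules, not samples: all
depth-variants of a molecule land on the same side.  This is stricter
than splitting samples at random but is the only choice that makes
validation loss meaningful at small scale, where a molecule's three
depth spectra are near-duplicates.

### The fixture-molecule generator

Tests and examples use generated molecules, not shipped data.  The
generator draws metabolite-like structures over C/H/N/O: random branched
skeletons of 5–10 heavy atoms (element probabilities C 0.60 / O 0.22 /
N 0.18), with a 35% chance of one ring closure, a 45% chance of one
carbonyl, and a 30% chance of building on a five- or six-membered
aromatic scaffold (benzene, pyridine, furan, pyrrole, imidazole)
instead.  Every product is RDKit-valid, canonical, unique, under 500 Da
protonated, and carries at least one breakable bond.  These proportions
were fixed once as a reasonable cartoon of small-metabolite space.

What the generator does **not** emulate: real spectra's noise peaks,
contaminants, missing fragments, rearrangement products, adducts beyond
protonation, and intensity structure.  Passing the toy-scale tests
therefore demonstrates that the architecture and pipeline can invert the
package's own fragmenter — a capacity and correctness statement — not
that a toy model generalises to measured spectra.  Generalisation at
full scale additionally requires training on millions of molecules.

## The transformer

Standard encoder–decoder attention architecture with pre-norm residual
blocks: source embedding over 50,001 tokens (50,000 bins + padding row),
target embedding over the 69-token vocabulary, fixed sinusoidal
positions, multi-head attention (causal mask in the decoder self-attention,
padding masks throughout), position-wise ReLU feed-forward
layers, and an untied output projection.  The reference configuration
(12+12 layers, width 1024, 16 heads, feed-forward 4096, dropout 0.2)
counts 404,061,253 trainable parameters by the closed-form sum, which
the test suite verifies against instantiated models across a
configuration sweep.  The bin-index token reading of the input is what
reconciles a 100-token maximum input length with a ~400M parameter
budget: the input embedding alone contributes 51.2M.

The implementation is pure NumPy — forward pass, manual backpropagation
and Adam — written for CPUs at research scale.  Gradient correctness is
tested directly against central finite differences.  Pre-norm residuals
were chosen over post-norm for optimisation stability at small width;
the parameter-count difference is two layer-norm vectors per stack.

Training minimises next-token cross-entropy (no label smoothing) with
Adam (β₁ = 0.9, β₂ = 0.98, ε = 1e-9) under the inverse-square-root
schedule `lr = s · d^-0.5 · min(step^-0.5, step · warmup^-1.5)` with
warmup 8000 at full scale, where the scale factor `s` is linear in
batch_size / base_batch_size (reference batch 896).  Validation loss is
evaluated every epoch; the best-validation weights are checkpointed and
training stops after `patience` epochs without improvement.  Toy runs
use warmup 300 and batch 32 with `base_batch_size` set equal to the
batch so the scale factor stays 1.

Everything is seeded: data shuffling, dropout and sampling use separate
`numpy` generators, so identical seeds reproduce loss histories and
predictions bit-for-bit on the same platform.

## Prediction and post-processing

Decoding is stochastic by design: the model is run `n` times (100 for
plain queries, 300 per top-k round at full scale; toy tests use 25–50)
with multinomial sampling at temperature 1.0, stopping at `<eos>`.
Invalid SMILES are discarded but counted; survivors are canonicalized
and tallied.  The ratio of unique predictions to runs is a certainty
signal — a confident model repeats one answer; an unsure model scatters.
Beam search would defeat this mechanism, which is why sampling is the
only decoding mode offered besides greedy reconstruction.

**Formula filter.** Since the precursor's exact mass pins the molecular
formula, predictions whose protonated monoisotopic mass falls outside
the ppm window (or which fail exact formula equality, when the formula
is known) are removed.  An empty result is meaningful and preserved as
the explicit "no prediction" outcome.

**Top-k intensity protocol.** For measured spectra, intensity correlates
with trustworthiness.  For k = 1..n_peaks the k most intense peaks
(ties toward lower m/z) are taken, sorted ascending in m/z, encoded and
decoded `n_runs_per_k` times; each round is formula-filtered and all
rounds are pooled with summed frequencies.  The final candidate is the
most frequent canonical SMILES.  Theoretical spectra can enter this
protocol via surrogate intensities that rank peaks by the depth at which
they first appear (precursor highest).

**Round-trip ranking.** Each candidate is re-fragmented and its binned
theoretical spectrum scored against the query with binary cosine
similarity |A∩B| / √(|A|·|B|).  Ordering is cosine descending, then
prediction frequency, then lexicographic canonical SMILES — the
tie-break chain is a package choice made for determinism.

**Similarity.** The TYPICAL similarity is the maximum Tanimoto
coefficient over six RDKit fingerprints (path-based, atom-pair,
topological-torsion, MACCS keys, Morgan radius-2, pattern), reported
together with the encoding that attained it.  Challenge-style scoring
marks an outcome `correct` on canonical-SMILES equality,
`no_prediction` when the formula-filtered set is empty, and `unknown`
otherwise, with the best Tanimoto (single path-based fingerprint by
default, TYPICAL behind a flag) reported for diagnosis.  Together with
the formula filter this yields Las-Vegas-like behaviour — correct answer
or explicit abstention — which the tests assert statistically on the
overfit fixture set.

## Numerical and design notes

- Atomic masses are most-abundant-isotope values at ≥ 6 decimals
  (H 1.0078250319, C 12, N 14.0030740052, O 15.9949146221; proton
  1.00727646).  Reference masses reproduce only at full precision.
- Formula enumeration over {C,H,N,O} (S, P, halogens behind the element
  list) prunes by mass bound per element, requires ring-plus-double-bond
  equivalents ≥ 0, applies no nitrogen rule, and sorts by absolute mass
  deviation.  It is tested against a nested-loop oracle below 200 Da.
- Parameters and activations are float32; losses accumulate in float64.
- Degenerate inputs fail loudly: empty spectra, non-positive masses,
  step 0 of the schedule, and vocabulary mismatches raise `ValueError`
  rather than propagating garbage.
- Test-suite problem sizes: 50 fixture molecules (150 samples), toy
  model 2+2 layers at width 64, 200 training epochs, 25 decoding runs
  per top-k round.  These sizes were chosen so a single-CPU run of the
  whole suite, including training, completes in minutes.

## Known limitations

- Positive-mode, protonated ions only; sodiation and other adducts are
  a configuration hook, negative mode is out of scope.
- No intensity prediction: the fragmenter emits presence/absence only.
- No rearrangements, no isotope patterns, no stereochemistry.
- The full-scale model is describable and countable here, but its
  weights are not shipped; headline identification accuracy on measured
  spectra requires full-scale training on millions of molecules and is
  out of scope for this package's tests.
- Latent-space candidate expansion around a top hit (an external
  generative-autoencoder search) is supported only through the
  `expand_candidates` hook.
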