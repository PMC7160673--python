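# Methods

## Library model

The Kme-OPL is modeled combinatorially: a set is the triple (methyl order ∈
{0,1,2,3}, fixed flank position ∈ {−3,−2,−1,+1,+2,+3}, fixed residue from
the 19-letter alphabet), giving 6 × 19 = 114 sets per methyl order. The
alphabet is the 20 standard amino acids minus cysteine (excluded by the
synthesis chemistry), kept in one-letter alphabetical order so every matrix
layout and enumeration is reproducible. The central position is always a
lysine carrying the methyl-order tag; it is never part of the degenerate
alphabet. Set identifiers serialize as `Kme{m}_P{±k}_{residue}`. A
consequence used throughout testing: every cysteine-free seven-mer of a
given methyl order belongs to exactly six sets, one per flank position.

The seven-mer window is treated as the complete informative unit; flanking
context beyond P±3 (glycine framing in synthesized validation peptides) is
outside the model.

## Signal pipeline

Replicate reader wells are aggregated by arithmetic mean and the matched
GST-only control mean is subtracted, clamped at zero — a floor consistent
with score ranges that start at 0, and with the interpretation that a reader
cannot bind less than not at all. When a well lacks a matched control, a
background level is chosen by comparing the unmethylated-pool (Kme0) signal
to user-supplied low and high reference levels: the nearer reference wins,
ties go to the high reference (conservative: over-subtraction can only
suppress apparent binding, never fabricate it). The distance-and-tie rule is
this package's own; only the Kme0-pool heuristic itself is inherited from
the assay design.

Profiles are 6 × 19 matrices of subtracted means; the normalized twin
divides by the matrix maximum so the brightest set is 1 (an all-zero matrix
stays all-zero and the profile is flagged "no binding"). Methyl-order calls
take the argmax of subtracted pool signals and co-report any order within
10% of the maximum — a numeric stand-in for the qualitative dual-order
(me2/me3) readers; the 10% tolerance is a package choice. The specificity
index is the fraction of the 114 normalized set signals at or above 0.5;
labels are `specific` (≤ 0.15), `promiscuous` (≥ 0.5), `intermediate`
otherwise. The two thresholds are package choices calibrated to the extreme
archetypes: a one-hot reader has index 6/114 ≈ 0.053 and a fully tolerant
reader 1.0.

## Lowest-Bin scoring

Every lysine in a FASTA proteome with at least three residues on each side
defines a seven-mer window. The LoB score is the minimum of the six raw
(RFU-scale) profile lookups; the raw matrix is used rather than the
normalized one so that scores stay on the RFU scale, with
normalization applied only for cross-scan comparison (ranks are invariant to
the choice, which is tested). Despite the historical "Lowest Bin" name the
computation is on continuous signals; no discretization is applied.

Exclusions are explicit rather than silent: lysines within three residues of
a terminus (`near_terminus` — the min rule cannot evaluate a missing
position and padding would fabricate signal), windows containing cysteine
(`contains_C` — the library never measures C), and windows with ambiguity
codes (`ambiguous_residue`). Excluded motifs carry no score, so scan totals
reconcile against the proteome's lysine count.

Ranking is descending by score with ties sharing the minimum rank; row order
is made deterministic by (rank, protein id, K position). Optimal/worst
sequence prediction takes the per-position argmax/argmin with exhaustive tie
reporting; the primary answer uses the lexicographically smallest residue,
and a position whose column is constant is reported as unconstrained. The
per-position argmax provably attains the global LoB maximum (the min of
column maxima upper-bounds every motif and is attained), which the suite
verifies exhaustively on a reduced alphabet.

Abundance annotation joins copy numbers (particles/cell) and reports
`fold_abundance` = copy(reference)/copy(protein), the factor by which an
abundant reference such as histone H3.1 outnumbers each candidate target.

## Fluorescence polarization

Readings in mP are scaled so the lowest-protein point sits at the requested
20 mP — the "scaled to the last dilution" step is interpreted as
proportional rescaling anchored at the lowest concentration of a serial
dilution (documented here because the sentence is ambiguous; the anchor and
request are overridable). Polarization converts to anisotropy by
A = 2P/(3−P) (inverse P = 3A/(2+A)), and curves are fit by bounded
least-squares to `A(x) = baseline + (amax − baseline)·xʰ/(kdʰ + xʰ)` with
initial values Kd = geometric mid-concentration, Hill = 1, amplitude and
floor from the data extrema, plus three seeded random restarts on failure.
A fitted baseline is included by default — the instrument reads a nonzero
floor at zero binding, which the 20-mP anchoring implies — but a
zero-baseline mode is exposed since either convention is defensible.

Reliability is flagged separately from convergence: a fitted Kd outside
0.01×–100× of the measured concentration range is unconstrained by the data
(the "too weak to determine" case). Ligand depletion is ignored (10 nM
ligand against Kd ≥ 0.1 µM); a warning fires if the fitted Kd comes within
10× of the ligand concentration. Flat curves are reported as
non-converged rather than fit.

## Synthetic-data generator

Binding is modeled as independent multiplicative occupancy per position:
each (position, residue) has a weight w ∈ (0,1], each methyl order a
multiplier (preferred = 1, others default 0.05 — near-background binding at
non-preferred orders, as methyl-dependent readers show). Over the equimolar
mixture the expected set signal has the closed form
S0 · order_weight · w(p,a) · Π_{q≠p} mean_r w(q,r), and the pool
S0 · order_weight · Π_q mean_r w(q,r); the mean over the 19 sets at any
fixed position equals the pool expectation exactly, an algebraic identity
the suite checks to machine precision. This mixture dilution is what makes
the specific-reader/low-pool-signal phenomenon emerge: a one-hot reader
multiplies five mixture means (≈ 1/19 each) into even its best set.

Plate wells add a GST/antibody background (default 150 RFU) to the
expectation plus Gaussian noise (default SD 50 RFU) truncated at zero, with
4 replicate wells per measurement; no noise model is inherited from the
assay, so truncated Gaussian is the minimal choice. Defaults
(S0 = 2000 RFU) put a fully promiscuous reader's pool at ~2,000 RFU,
matching the magnitude promiscuous readers show. Because mixture dilution
scales specific readers' set signals down by ~19⁵ relative to S0, one-hot
models accept a `peak_set_signal` calibration that solves for S0 such that
the brightest set's expectation lands at a stated RFU level; the recovery
experiments use 800 RFU, the scale of top sets in real screens, with the
default 50-RFU noise. Without this calibration a one-hot model at the
default S0 would have sub-RFU set expectations and the plates would be pure
noise.

The proteome generator draws i.i.d. residues (uniform over all 20 standard
amino acids by default, so cysteine occurs as it does in real proteomes)
with lengths uniform on 200–400, and plants specified K-centered seven-mers
at least three residues from termini, emitting a ground-truth manifest. The
FP generator evaluates the Hill model, adds Gaussian noise on the anisotropy
scale, and converts back to mP. All generators are bit-reproducible from
their seed.

### What the simulator does and does not capture

It emulates position-independent sequence preference, methyl-order
dependence, antibody background, replicate noise, and mixture dilution. It
does not model cooperative/conformational effects (e.g. β-hairpin induction
where one position's contribution depends on another), bead or wash
kinetics, signal saturation, plate edge effects, or correlated noise.
Passing recovery tests therefore demonstrates the pipeline's correctness
under the stated generative assumptions, not that real readers are
position-independent.

## Validation experiment sizes

The recovery experiments use 100 simulated plate/proteome replicates
(100 proteins each, one planted motif) for motif recovery, and 100
simulated titrations (12-point serial dilution 0.01–100 µM, four replicate
curves averaged per titration as in the assay's replicate design, noise SD
5% of the saturation amplitude) for Kd recovery; these sizes give stable
fractions and medians while keeping a full run in seconds.

## Known limitations

- Pool screening under-reports extremely specific readers (their pool
  expectation can sit at noise level), so a methyl-order call from pools can
  be a false negative — a limitation of the assay design itself, which the
  simulator reproduces.
- LoB treats positions independently; a motif scored high may still fail to
  bind if recognition requires cooperative context.
- The Hill fit assumes free ≈ total protein; strong binders approaching the
  ligand concentration need a depletion-aware model.
- Exclusion of cysteine-containing windows means the scan is silent about
  ~a quarter of real proteome motifs; they are reported as excluded rather
  than scored.
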