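# Methods

## Model

The package measures self-entanglement of a protein domain treated as an
open, oriented discrete curve through its alpha carbons.  For two
non-overlapping portions of the chain the Gaussian entanglement G′ is the
Gauss linking integrand evaluated with the midpoint rule over all segment
pairs: segment midpoints R_a, bond vectors ΔR_a, and summand
(1/4π)(R_a − R_b)/|R_a − R_b|³ · (ΔR_a × ΔR_b).  For closed polygons this
discretization converges to the integer linking number as the polygons are
refined; on open portions it yields a real number whose magnitude counts
mutual windings and whose sign encodes chirality for chains oriented from
the N to the C terminus.

A *loop* is a portion whose end residues are in native contact — some
non-hydrogen atom of each residue strictly closer than 4.5 Å — with
sequence span at least m_i = 4.  A *thread* is any contiguous portion of
span at least m_j = 10 lying entirely N-terminal or C-terminal of the
loop; loop and thread may share a boundary residue (their segment sets
stay disjoint) but no exclusion buffer is applied beyond non-overlap.
Per loop and side, the thread maximizing |G′| is selected with the sign
retained; per domain, GN′ and GC′ are the signed values of the
maximum-modulus pair per side over all loops, and Gmax′ is the
larger-modulus of the two.  Maximizing the modulus (rather than the
signed value) at every level keeps negative-chirality motifs
discoverable; this is the package's resolution of a genuinely open design
point at the per-loop level, made so that the sign structure of the
population histogram is preserved.  A domain counts as entangled when
|Gmax′| ≥ 1 (one full winding); the looser 0.5 threshold used in
misfolding contexts is available as a configuration option but is not the
default.

Determinism: candidate pairs tied in |G′| to 1e-12 are resolved by the
smallest thread start, then smallest thread end; ties across loops by the
smallest loop start, then end.  When |GN′| = |GC′| exactly, the N side is
reported as the maximum.

## Algorithmics

The kernel matrix K(a, b) over all segment pairs is computed once per
domain, O(N²).  For a fixed loop, the G′ of every candidate thread is a
contiguous sum of per-segment totals g(b) = Σ_{a∈loop} K(a, b), so the
maximum-|G′| span with a minimum-length constraint is found by a prefix-sum
scan tracking running extrema — O(N) per loop instead of O(N²).  Cumulative
row sums of K make g(b) itself O(N) per loop.  The scan is proven equal to
direct per-span evaluation of the double sum in the test suite (random
chains, every legal span enumerated from the raw kernel block).  Adjacent
segments are included (their midpoints are distinct); the diagonal
K(a, a) is zero, matching the absence of a self-term.

## Structure handling

PDB files are parsed with gemmi; only the first model is used (X-ray
convention; NMR ensembles are out of scope).  Alternate locations reduce
to the highest-occupancy conformer, ties broken by the lexicographically
first altloc indicator.  Waters are removed; hydrogens are kept but
excluded from contacts by element symbol.  MSE is treated as a standard
residue (selenomethionine is a crystallography artifact); all other
heteroatom residues are dropped.  These conventions are ours: structure
annotation practice varies and no single convention is canonical.

Domains are single contiguous residue ranges in author numbering;
multi-fragment domains are rejected, since backbone continuity is what
makes self-entanglement well defined.  Residues requested but absent from
the coordinates are treated as unresolved: terminal runs are dropped
(tails are not modeled, to avoid spurious backbone entanglement), internal
runs of at most 10 residues are bridged, and a longer internal run rejects
the domain.  Bridging places the missing alpha carbons by deterministic
linear interpolation, equally spaced between the flanking observed ones.
Template-based loop reconstruction would give more realistic gap geometry;
linear interpolation is deterministic, dependency-free, and can shift G′
by at most a few hundredths for gaps of this size, because reconstructed
residues carry no heavy atoms and therefore never open loops — they only
contribute curve geometry.  Missing residues are detected as author
numbers absent from the requested range in the coordinate records, which
for single-model entries is equivalent to reading the unobserved-residue
remarks and is robust to absent headers.

## Membrane classification

Chain-level annotation records carry two boolean database flags (PDBTM,
MemProtMD) and two free-text annotation strings (mpstruc, OPM).  Topology:
transmembrane if the PDBTM flag is set or "transmembrane" appears as a
whole word (case-insensitive) in the text; monotopic if "monotopic"
appears.  Persistence: integral if either database flag is set or any of
"transmembrane"/"intrinsic"/"integral" appears; peripheral if
"peripheral" appears.  If both rules of a label fire, or neither, the
label is `unclassified`: conflicting records are surfaced for manual
review rather than silently resolved, and word-boundary matching prevents
substring false positives.

## Survey statistics

All statistics operate on a tidy per-domain table.  The signed-Gmax′
histogram is density-normalized with 0.1-wide bins aligned so that 0 and
±1 are bin centers.  The survival function at threshold x is the fraction
of domains with |Gmax′| strictly greater than x; the modulus convention is
used because a signed survival axis could not start at 1 in the presence
of negative-chirality domains.  Grouping fractions partition survivors by
kind and chirality of the dominant motif — GN′>GC′>0, GC′>GN′>0,
GN′<GC′<0, GC′<GN′<0 — counting only domains whose two side indicators
share a strict sign; opposite-sign (anti-diagonal) domains and domains
with an absent side stay in the denominator but in no group, since mixing
topologically different arrangements into one group would not be
meaningful.  Thresholds with zero survivors report missing values, not
zeros.  Uncertainty bands are domain-level bootstrap percentiles
(default 10,000 resamples, 5% and 95%), resampling rows with replacement;
the generator seed (default 20230524) is configurable and fixed for
reproducibility.

## Synthetic ground truth

The generator builds single open chains whose entanglement is known by
construction.  The loop is a near-circular arc (CA spacing 3.8 Å) in the
z = 0 plane whose end residues face each other across a 5.6 Å gap and
carry dummy CB atoms 3.6 Å apart, forcing exactly the intended closing
contact through the heavy-atom rule as written.  The thread is a helix of
tube radius 8 Å and pitch 6 Å per turn winding m times around the loop
wire — each turn contributes one linking unit — with handedness setting
the chirality.  Non-entangled chains use a fractional (0.3-turn) winding,
yielding |G′| ≈ 0.2, the shoulder value typical of non-entangled native
domains.  Connectors and entry/exit legs are routed exactly in the loop
plane: a curve coplanar with a planar loop has identically zero Gaussian
coupling with it (every scalar triple product of coplanar vectors
vanishes), so the legs cannot contaminate the planted winding number —
a sharper guarantee than keeping the legs merely far away.  Each side of
the loop owns a private angular sector of the plane so paths never
approach within contact range; chains are resampled at a constant 3.8 Å
chord, and optional Gaussian vertex noise (σ = 0.1 Å for the study
conditions) is applied to all alpha carbons.  Helix handedness-to-sign
calibration constants were fixed once against the refined Gauss-integral
oracle.

Two-sided chains place independent thread sections on both sides of one
loop to plant same-sign (diagonal) or opposite-sign (anti-diagonal)
GN′/GC′ combinations for the grouping statistics.  Cohorts draw class
counts as rounded expected counts, so planted compositions are exact up to
rounding; per-chain noise uses independent substreams of the cohort seed.

What the generator does *not* emulate: dihedral-angle statistics, sterics,
secondary structure, sequence realism, or the contact density of real
folds (synthetic chains have exactly one forced contact).  Passing tests
therefore demonstrate the correctness of the measurement pipeline on
curves of known topology, not the biological distribution of entanglement;
real-structure surveys additionally depend on database snapshots, domain
boundary assignments and homology filtering, which are inputs here.

## Problem sizes and numerical choices

The test suite and the acceptance script use loop sizes of 30–40 residues
(chains of roughly 95–180 residues), 200 noisy constructions for the
recovery rate, cohorts of 120–200 domains, and 500–10,000 bootstrap
resamples; these sizes give sub-percent Monte-Carlo error on the reported
rates while keeping a full run in well under a minute.  Closed-curve
checks use 200–400 segments, where the discretization error of the
linking integral is below 3·10⁻⁴.  Kernel entries are dense float64; a
non-finite entry (coincident midpoints of distinct segments, a
zero-measure configuration) raises rather than being silently patched.

## Known limitations

* Inter-chain entanglement (domain-swapped complexes) is out of scope;
  the survey treats single domains.
* Gap bridging is linear, not template-based; worked-example indicator
  values for gapped real structures can differ from template-modeled
  reconstructions by a few hundredths.
* Ligand heteroatoms are excluded from the contact search; contacts are
  amino-acid residues only.
* Insertion codes are collapsed onto the numeric author identifier when
  cutting domains, which is exact for the numbering schemes handled here
  but would mis-order chains that interleave insertion codes within a
  requested range.
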