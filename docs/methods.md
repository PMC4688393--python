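# Methods

This note records the models `flakit` implements, the defaults it ships,
and the choices made where the underlying conventions were genuinely open.
Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and input formats

All sequence coordinates are 1-based inclusive; the gene-locus table's
`ChrNN: start–end` positions satisfy `end − start + 1 = gene length` and
`ORF/3 − 1 = protein length` (stop codon excluded), and both identities
are verified on every read. En-dash and hyphen separators are both
accepted. Strand is not modelled — the table provides none, and all
protein-level logic is strand-agnostic; this is a documented limitation.
Amino-acid sequences admit the 20 standard letters plus X; anything else
is rejected rather than silently remapped.

## Glycomodule grammar

Hydroxyproline is not observable from sequence, so Pro stands proxy for
Hyp throughout, as is standard for sequence-level AGP scans. An
*O*-glycosylation site is an [A/S/T]-Pro dipeptide; its Pro run length is
recorded in full and capped at 4 for rule purposes (runs longer than 4
still qualify). Two sites can never share residues, so "non-contiguous"
is automatic. Sites are clustered transitively: consecutive sites merge
when the gap between one site's final Pro and the next site's [A/S/T] is
≤ 10 residues — the pairwise [A/S/T]-Pro-X(1–10) spacing applied along a
chain, with a gap of 0 (the direct [A/S/T]-Pro-[A/S/T]-Pro repeat) also
allowed, since the canonical shortest region is the 4-residue `SPTP`.
A cluster is a module if it has ≥ 2 sites (`paired_sites`) or one site
with run ≥ 2 (`single_run`); the module spans first [A/S/T] to last Pro.
Module boundaries are this package's convention — the source conventions
name only the site-level rules. Sites overlapping excluded intervals
(fasciclin domains, terminal signals) are discarded before clustering.

PAST composition is the percentage of P+A+S+T residues; X counts toward
length but never toward PAST.

## Fasciclin-domain detection

The detector scores three conserved blocks — H1 (10 columns), [Y/F]H (2),
H2 (10) — with per-column log-likelihood ratios against a uniform 1/20
background. Column weights come from a **synthetic** seed alignment built
from the described residue preferences (invariant Thr in H1 with Asp/Asn
six positions downstream, H1 otherwise rich in A/I/F/P/S, H2 ending in
V/L/I, [Y/F]H tolerating the observed F-for-H and E/K/L/H-for-Y/F
substitutions at a score penalty), with add-one smoothing over the
20-letter alphabet. The real alignment behind those block definitions is
not machine-readable, so the packaged seed is an explicit stand-in and the
detector's scores are not comparable to profile-HMM E-values; importing
coordinates from a dedicated domain scanner remains the high-fidelity
path.

Candidate domains are H1…[Y/F]H…H2 triples spanning 110–150 aa in block
order; overlaps are resolved greedily by total score (ties to the
leftmost start) and at most two domains are reported per protein. The
default thresholds (H1/H2 ≥ 8, [Y/F]H ≥ 1, total ≥ 22 nats) were placed
above the upper tail of a residue-permutation null
(`permutation_null_scores`; observed null maxima ≈ 13 on FLA-length
proteins) and far below the score of profile-sampled domains (≈ 35–40).
On 200 synthetic proteins the scan's recall and precision both exceed
0.95 (tested).

## Terminal signals

The built-in heuristics are deliberately lightweight conveniences;
imported predictions always take precedence and carry `source=imported`.

* **Signal peptide** — a hydrophobic window (length 8–20, mean
  Kyte–Doolittle ≥ 1.6) inside the first 40 residues, preceded by ≤ 5
  residues containing ≥ 1 positive residue; reported end = window end + 3
  as a cleavage guess.
* **GPI signal** — within the last 40 residues, an ω-site candidate with
  small residues (A/S/G/N/D/C) at ω and ω+2, followed 3–10 residues later
  by a hydrophobic stretch (mean KD ≥ 1.5, ≥ 5 residues) running to the
  C-terminus.

## Membership and groups

`is_fla` requires a fasciclin domain AND a qualifying glycomodule outside
the excluded intervals AND a signal peptide; GPI is optional. Groups are
assigned in order: two domains with ≥ 1 module strictly between, no GPI,
and protein length within the group-B envelope (default 400–500 aa) → B;
one domain with modules strictly on both sides → C if length ≥ 350 aa
else A; anything else → D. The A/C length split is a package decision:
the two groups share an architecture and the published members separate
cleanly by length (A ≈ 227–283 aa, C ≈ 397–421 aa), so 350 aa sits in the
gap; it is configurable (`GroupRules`). Two-domain proteins outside B's
envelope fall to D, matching the one published two-domain outlier. An
alternative reading assigns groups from tree clades; this package
implements the architecture reading.

## Phylogenetics

Global alignment is Needleman–Wunsch with affine gaps via Biopython's
`PairwiseAligner` (BLOSUM62, open 10, extension 0.1 — Clustal-style
penalties). Identity is matches over alignment columns (dual-gap columns
excluded); similarity additionally counts positive-scoring pairs.

Distances are p-distance with pairwise gap deletion by default, or
Poisson-corrected (−ln(1 − p)); the published tree's distance model is
unstated, so exact topology reproduction is out of scope and grouping
behaviour is the tested surface. Neighbor joining follows the Saitou–Nei
Q-criterion with deterministic tie-breaking (lowest index pair); negative
branch lengths are clamped to zero with the deficit moved to the sister
edge, preserving the joined pair's path length (the MEGA-compatible
convention). Bootstrap resamples alignment columns with replacement and
reports the percentage of replicates containing each original
bipartition; zero-variation alignments are flagged in the output rather
than raised. On additive matrices NJ recovers the generating tree exactly
(topology and branch lengths; tested to 30 leaves, cross-checked against
scikit-bio's independent implementation).

## Ka/Ks and dating

The counting method is NG86 because it is fully specified and
desk-verifiable: per-codon synonymous site fractions from the nine
single-base mutants (mutants creating stops are excluded from the
denominator, so every position contributes one site and S + N = 3 per
codon), sites averaged over the two sequences, differences averaged with
equal weight over minimal mutational pathways (pathways through stops
excluded; if every pathway is blocked they are all kept so differences
are still counted), Jukes–Cantor correction, Ka/Ks reported as missing —
never infinity — when Ks = 0. p ≥ 3/4 raises a "saturated" error. The
published pair table was produced with a codeml workflow, so exact Ka/Ks
parity is not expected; the dating surface T = Ks/(2λ), λ = 9.1×10⁻⁹ for
*Populus*, depends only on Ks and reproduces the published ages from the
printed Ks values to 0.1 MYA on 12/12 rows (one row differs by the
source's own rounding: Ks = 0.3196 → 17.56 MYA, printed 17.5).

Duplication typing is the chromosome-sharing dichotomy (same chromosome →
tandem), which is exactly the published 3-vs-9 split; an optional
`max_separation` parameter tightens tandem to proximal pairs for stricter
definitions.

## Expression

ΔΔCt: replicate Ct values are aggregated by arithmetic mean before ΔCt
(the aggregation rule is unstated in common practice writeups; the mean
is the Livak convention), fold = 2^−ΔΔCt with perfect doubling assumed
(no efficiency correction). The calibrator defaults to the
maximum-ΔCt (lowest-expressed) sample, the convention for tissue panels
plotted relative to the weakest transcript, and can be overridden.
Adding a constant to all Ct values of a sample cancels in the reference
subtraction (tested). ANOVA is the standard one-way F; Tukey HSD letters
are assigned from maximal cliques of the not-significantly-different
graph, which guarantees that groups sharing a letter are never
significantly different pairwise. Heat-map rendering is a thin layer over
the tested matrix math (log₂ with pseudocount, applied at most once).

## Synthetic data

The generators define the study conditions for testing:

* **Proteomes** — filler sequence contains no Pro, so every glycomodule
  is planted; non-GPI proteins end in charged residues (DEK) so the
  hydrophobic-tail heuristic cannot fire spuriously; fasciclin blocks are
  sampled column-wise from the packaged seed alignment (no external
  sequence data is shipped). Group lengths follow the published regimes:
  A < 300 aa, B ≈ 430–480 aa, C ≈ 390–440 aa, D outside those envelopes.
  `make_reference_family` plants the published composition exactly
  (23 A / 4 B / 4 C / 4 D, 23 of 35 with GPI) among distractors.
  These proteins are architectural cartoons: passing tests shows the
  scanner/classifier logic is correct on sequences that obey the stated
  grammar, not that the heuristics match dedicated predictors on real
  proteomes.
* **CDS pairs** — a random sense-codon ancestor diverges along two
  lineages; synonymous/nonsynonymous events are Poisson in number at the
  requested per-site rates, target codons in proportion to their current
  mutable-site counts, and may stack or revert, so realised divergence is
  a genuine multiple-hit process and NG86+JC recovers the simulated Ks
  within 10% at rates 0.05–0.2 (tested, 20 × 1000-codon replicates).
* **Ct tables** — built by inverting the ΔΔCt model around a reference
  gene (Ct 20, base ΔCt 5) with Gaussian replicate noise; zero noise
  inverts exactly. The 0/12/24 h × triplicate salt-stress layout is the
  default design in the examples.
* **Trees** — random binary topologies with uniform(0.05, 0.5) branch
  lengths and exact path-length distances; two-clade alignments for
  bootstrap checks.

All generators are pure functions of (parameters, seed).

## Problem sizes in the default test run

The suite exercises 1,000 random sequences against the glycomodule
oracle, 500 random codon pairs against the NG86 pathway oracle, 20
replicates × 1,000 codons per rate for Ks recovery, 200-protein proteomes
for classifier recovery, trees to 30 leaves, and 200 bootstrap
replicates — sizes chosen so the whole suite completes in well under a
minute while leaving the statistical margins (10% Ks tolerance, 95%
recovery) comfortably wide.

## Known limitations

* Signal/GPI heuristics are low-fidelity stand-ins; import dedicated
  predictions for real analyses.
* The fasciclin seed alignment is synthetic-consensus-based; scores are
  package-internal, not E-values.
* Strand, UTR conventions and genome-level synteny are out of scope;
  duplication typing uses chromosome sharing only.
* NG86 is a counting method; maximum-likelihood Ka/Ks (codeml-class
  models) is intentionally not reimplemented.
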