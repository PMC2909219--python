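# Methods

This note documents the models, estimators, numerical choices and
limitations of `matescaf`. Notation: contig $i$ has stored sequence of
length $M_i$, orientation $S_i \in \{\pm 1\}$ ($+1$ = stored sequence reads
left-to-right in the scaffold) and start coordinate $x_i$; a read placed at
0-based offset $p$ with length $\ell$ occupies contig interval
$[p, p+\ell)$, with $\tau = +1$ when the read matches the contig forward
strand.

## Pair geometry

A read's scaffold-forward position is $x_i + p$ for $S_i = +1$ and
$x_i + M_i - p - \ell$ for $S_i = -1$; its scaffold strand is $\tau S_i$.
A SOLiD mate pair has both reads on one genome strand with F3 to the right
of R3; an Illumina paired-end has the reads on opposite strands facing each
other. Writing $g = \tau_R S_{i_R}$ for the strand of the R read, both
library types impose the single linear constraint

$$g \cdot \big( (x_{i_F} + \mathrm{rel}_F) - (x_{i_R} + \mathrm{rel}_R) \big) = \mathrm{Ins},$$

where the insert $\mathrm{Ins}$ is defined as the separation of the two
reads' start coordinates in genome orientation. The orientation parity is
$\tau_R\tau_F$ for mate pairs and $-\tau_R\tau_F$ for paired-ends. Each
cross-contig pair therefore yields a parity vote and an implied offset
$x_j - x_i$, stored for the canonical choice $S_i = +1$ of the
lower-named contig; the value under the flipped choice follows from
reflecting the layout, $x' = -(x + M)$. A zero-noise simulation reproduces
every true offset exactly through this algebra (tested).

## Edge construction and background removal

Per contig pair, links are split by parity. If the dominant group holds at
least the majority fraction (default 0.7) the minority is dropped and
$J_{ij} = \pm(\text{dominant count})$; otherwise all links on the edge are
ignored — balanced parity votes are the signature of repeats or chimeras,
not of sampling noise. Libraries show a broad background of pairs whose
separation is uniform rather than peaked at the insert; a background link's
implied offset is arbitrary within the geometrically feasible band, so on
each edge links deviating from the median implied offset by more than
2.5σ are dropped, and if that filter removes more than the minority
fraction the edge as a whole is discarded (a genuine edge's separations
cluster; a background edge's do not). Edges with fewer than $W$ (default 5)
surviving links are ignored, as are contigs shorter than $L$ (default
150 bp). Defaults for $W$ and $L$ are working values for a ~100× bacterial
mate-pair assembly.

## Insert-size estimation

Same-contig pairs with library-consistent orientation give measured
separations $\tau_R (p_F - p_R)$. Separations farther than the nominal
insert from the nominal insert (≈ 5σ under the 20%-of-mean rule) are
outliers; the empirical insert and σ are the mean and standard deviation of
the remainder. When every pair is an outlier the nominal insert with
σ = 0.2·Ins is used and flagged. Background pairs inside the acceptance
window bias the mean slightly low (≈ 2–3% at 10% background); the bias is
common to all edges and does not reorder contigs.

## Orientation assignment

$E[S] = -\sum J_{ij} S_i S_j$ is minimized per connected component.
Articulation vertices with more than two neighbors are split recursively
(each child keeps a copy of the vertex) until components are non-reducible;
because no edge crosses components, energies add, and the global optimum is
recovered by merging in reverse split order, using each child's global-flip
degeneracy to align the articulation copies. A flat (non-tree) merge is
incorrect: a part can share copies with two earlier parts at once.
Non-reducible components are layered breadth-first from a minimum-degree
start vertex; if every layer has at most 6 vertices an exact Viterbi sweep
over layer states is used, otherwise Metropolis annealing (start all $+1$,
$T_0 = 2\max|J|$, cooling $\alpha = 0.999$ per sweep, stop at $T < 10^{-3}$
or 50 improvement-free sweeps after cooling below $0.05\,T_0$ — the plateau
rule is gated on cooling because the best-seen energy is uninformative at
high temperature). Degeneracy is fixed by flipping each component so its
lowest-named contig is $+1$. Edges with $\mathrm{sign}(J_{ij}) \ne S_iS_j$
in the optimum are excluded from positioning.

## Positioning and the separation estimator

Positions minimize $\sum |J_{ij}|((x_j - x_i) - \bar d_{ij})^2$, solved as
the force-balance linear system of the weighted graph Laplacian with the
lowest-named vertex anchored at 0 (dense solve; components here are at most
a few hundred vertices). σ is the empirical per-pair standard deviation
from insert estimation.

The naive $\bar d_{ij}$ — the arithmetic mean of the implied offsets — is
conditionally biased: a pair is only observed on an edge if both reads fit
inside the contigs, which weights the Gaussian separation density by the
trapezoid of feasible read placements and truncates its tails. The bias is
roughly $\sigma^2 \partial_s \ln \ell(s)$ (ℓ the trapezoid), grows as
contigs shorten, and at σ = 270 reaches several hundred bases — larger than
the pruning threshold. The positioning step therefore uses a corrected
estimator: the fixed point of
$\delta = \bar d_{\text{naive}} - \mathrm{Ins} + \mathbb{E}[s \mid \text{linked}, \delta]$,
with the conditional mean computed by numeric quadrature (257-point grid
over the ±6σ window intersected with the feasible band, ~20 iterations,
tolerance $10^{-3}$). At σ = 0 it reduces to the naive mean, which remains
the quantity stored on the graph and reported.

Springs with residual $\Delta_{ij} > k\sigma/\sqrt{|J_{ij}|}$ (the standard
error of a mean of $|J|$ separations, times $k = 5$) are inconsistent; the
worst offender (largest residual-to-threshold ratio, ties by edge name) has
both endpoint contigs removed, and the pipeline returns to orientation.
Removing only the worst edge per iteration keeps good contigs when several
springs share one culprit; the loop terminates because the vertex count
strictly decreases.

## Density profile, Potts segmentation, juncture removal

The density profile is the per-base contig cover count averaged over
1000-base windows. High-density runs are windows ≥ 1.5 sustained for ≥ 2
windows (plateaus are near-integer; 1.5 separates 1 from 2 robustly, and
single-window spikes from small positional errors are not evidence of
fusion). The label count is $q = 1 + \sum_{\text{runs}}(\text{round(peak)}-1)$.

Potts couplings are $w_O O_{ij} - w_D D_{ij}$ with $w_O = w_D = 1$,
$D_{ij} = 1$ iff the contigs are directly linked, and $O_{ij}$ = positional
overlap length normalized by the mean contig length. Annealing shares the
orientation schedule with uniform random initial labels. Juncture
candidates are contigs with a differently-labeled graph neighbor. Removal
subsets are scored by
(removed contigs + components spanning < 2·Ins) + 5 × (remaining windows ≥ 1.5),
lower is better, ties to smaller then lexicographically earlier subsets;
removed contigs count as small components so that removing extra contigs
cannot hide fragmentation. The search is exhaustive up to 12 candidates
(4096 subsets), then restricted to candidates overlapping the densest run,
then a seeded random sample of 2000 subsets. Components whose profile is
still overloaded are re-segmented recursively; all removals are reported as
singletons.

## Joining and gap rendering

Adjacent contigs with positional overlap or an estimated gap below 10 bases
are merged if their facing ends align at ≥ 90% identity (banded
edit-distance over a window of max(2·|gap|, 30) bases, minimum 5-base
overlap so a chance single-base match cannot fire); at disagreeing overlap
columns the left contig's base is kept. Otherwise an 'N' spacer of the gap
rounded to the nearest multiple of 50 is inserted (ties round up, minimum
50); an unsupported positional overlap gets exactly 50 'N'. Gaps below 25
bases thus never silently vanish — the conservative choice when the
similarity test fails.

## Color-space translation

Colors obey XOR arithmetic on A,C,G,T → 0..3 (classes
{AA,CC,GG,TT}=0, {AC,CA,GT,TG}=1, {AG,GA,CT,TC}=2, {AT,TA,CG,GC}=3), so
fixing one base and the color chain determines everything — and propagates
any single color error to all downstream bases. The robust translator
scores a candidate sequence by $(1-r_c)$ per matching color and $r_c/3$ per
mismatch, times $(1-r_s)^{f}$ and $(r_s/3)^{f}$ over the per-position
first-base suggestion counts, and maximizes by a Viterbi pass over the four
base states per position, in log space, with ties broken toward the
alphabetically earlier base at every step (deterministic even in the
degenerate no-suggestion case, which is defined only up to the four-fold
color symmetry unless a reference base pins position 1). Defaults
$r_s = e_s$ (a suggestion is one read's first call) and
$r_c = \min(0.5, e_s/d)$ for coverage $d$ (a consensus color averages ~d
calls; any decreasing-in-$d$ form behaves equivalently over the tested
$[10^{-4}, 10^{-1}]^2$ rate grid). Error correction requires suggestion
density: with one suggestion per position a lone color error is corrected
across the whole rate grid; with only two isolated suggestions after the
error, the intervening base is unconstrained and very confident colors
($r_c \sim 10^{-4}$) can out-vote weak suggestions — the expected behavior
of the likelihood, not a defect. Indels are not modeled.

## The simulator and what it does not emulate

`simdata` generates i.i.d.-base genomes at a set GC content with optional
planted exact repeats; tiles them into contigs on random strands separated
by gaps (default: uniform multiples of 50 in [50, 300], matching the
renderer's grid so zero-noise round trips are exact); optionally injects
chimeras (two non-adjacent contigs concatenated) or a collapsed repeat (one
contig mapped to several genome loci); and draws mate pairs with
$N(\mathrm{Ins}, \sigma)$ separations (negative draws redrawn), the
platform strand geometry, and a uniform-coordinate background fraction.
Reads falling in gaps or straddling contig ends are discarded. Ground truth
records every contig's source intervals and strands, enabling exact
evaluation.

Not emulated: per-base quality variation, indel errors, non-uniform
(GC-biased) coverage, inexact repeats, and assembler-specific consensus
artifacts. Passing tests therefore demonstrate correctness of the
optimization machinery under the stated statistical model, not robustness
to every artifact of real libraries; on real data the permissive coverage
filter defaults (mean factor 2.5, local factor 3 over 100-base windows,
chosen to be safe at 40–100× coverage) and the self-consistency filter
(off by default; relevant for greedy contig assemblers prone to chimeras)
may need tuning.

## Evaluation

N50 is the smallest length such that pieces at least that long cover half
the assembled bases. Error metrics are computed against simulator truth
with the event definitions preserved: no-match (% assembled bases in
contigs absent from truth), mismatch (% bases differing from the genome at
truth coordinates, indel bases counted once), chimeric joins inside one
contig split at a 500-base true-gap threshold, orientation events (adjacent
pairs whose relative orientation disagrees with truth; an interior
inversion counts twice), and separation events (facing-end gap off by more
than 500 bases; facing-end gaps are used because start-to-start distances
are not invariant under reversing a scaffold, whose direction is
arbitrary). Rates are per Mbp of assembly. Adjacency recovery counts true
consecutive contig pairs reproduced adjacently with correct relative order
and orientation, global scaffold flips allowed.

## Study sizes

The reference scaffolding study uses ten simulations of a 200 kb genome in
80 contigs with insert 1350 bp, σ = 270 bp, 30× pair coverage and 10%
background — large enough that every edge statistic (majority filtering,
background clustering, bias correction, spring pruning, segmentation) is
exercised, while a full ten-seed study completes in well under a minute.
The oracle suites compare the exact and annealed solvers against
vectorized exhaustive enumeration up to 12 variables.
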