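# Methods

## The fingerprint transform

A sequence of length N over {A, C, G, T} (plus one ambiguity placeholder,
see below) is treated as a circle regardless of its deposited topology.
For target base n and focusing base m the relative distance is
RD(n, m) = ((m − n) mod N) with the value N substituted when the modulus
is zero: when the focusing base returns to the target it has travelled the
whole circle, so the distance is N, never 0.  Dividing by N gives the
weighted distance WRD ∈ (0, 1], and the per-class sums SWRD_B(n) collect
WRD over all positions carrying base B.  The coordinate triple at n is the
standard Z-curve combination of the four sums — x: purine−pyrimidine,
y: amino−keto, z: weak−strong.

Two consequences shape everything downstream:

* **Cutting-point invariance.**  RD depends only on the circular offset
  m − n, so re-cutting (rotating) the sequence relabels positions but
  leaves every physical base's coordinates unchanged; the track is the
  cyclic permutation of the original.  The cumulative-count Z-curve
  baseline (`zcurve_track`) is kept in the package precisely to exhibit
  the contrast: its coordinates count bases from the deposited first
  base and change shape under rotation.
* **Composition closed form.**  Σ_n RD(n, m) = N(N+1)/2 for every m, so
  the mean of each coordinate depends only on base composition:
  mean(x) = ((c_A+c_G) − (c_C+c_T))·(N+1)/(2N), and cyclically for y and
  z.  The geometric center is therefore a pure composition statistic,
  while the spread of the track around it carries positional information.

## Exact integer arithmetic

Both engines accumulate *unscaled* integer RD sums and divide by N only
when emitting coordinates.  This makes three properties exact rather than
approximate: engine equivalence, rotation invariance, and the per-position
conservation law Σ_B SWRD_B(n) = (N+1)/2 on unambiguous input.  The
accumulators are int64; the largest value, N(N+1)/2, stays in range for
any N below ~4×10⁹, far beyond real replicons, and a guard raises before
overflow could occur.  Geometric centers are emitted as correctly rounded
floats of the exact rational means (`Fraction`), so the closed-form
identity above holds bit-for-bit in tests.

## The O(N) engine

The naive definition is a double loop, O(N²).  Moving the target from n to
n+1 decreases every relative distance by one except for the focusing base
now coinciding with the target, whose distance wraps from 1 to N.  In
integer form, with c_B the count of class-B residues:

    S_B(n+1) = S_B(n) − c_B + N · [residue(n+1) = B].

The whole profile track is a cumulative sum over the base-indicator
matrix — one vectorized pass.  The naive engine is retained as the oracle;
its inner loop over the focusing base is vectorized but the work remains
quadratic, and the suite asserts exact equality of the two engines on 100
seeded random sequences up to 2 kb as well as on the worked 40-mer.

## Ambiguous bases

Real replicons contain runs of N and other IUPAC ambiguity codes.  All
such symbols collapse to a single placeholder that occupies its position —
it contributes to N and to every relative distance — but belongs to no
base class, adding zero to every SWRD component.  RNA input is handled by
mapping U to T.  The conservation law is asserted only on unambiguous
sequences; ambiguous positions lower the per-position total below
(N+1)/2 by exactly their share of distances.

## Summary statistics and comparison

* Geometric center: per-axis mean (exact, see above).
* Standard deviation: population form (divisor N).  No reference value
  exists to discriminate the divisor; the choice is recorded here and
  trivially switchable.
* Signed geometric mean: Gm = sign(x̄ȳz̄)·|x̄ȳz̄|^(1/3) — the side of the
  cube with the cuboid's volume, signed so that centers in different
  octants produce very different Gm.  Zero iff any component is zero.
* Dr = 100·|Gm_a − Gm_b|/|Gm_a + Gm_b|.  The denominator is the signed
  sum: near-cancelling opposite-sign geometric means blow the rate up,
  which is the intended behavior for genomes on opposite sides of a
  coordinate plane.  A vanishing denominator yields a flagged undefined
  value (serialized "/"), never an exception.
* WDr = Dr (in percent, full precision) × Ed, cross-weighting the
  rate by the absolute separation of centers; it is the recommended
  tie-breaker when Dr alone is misleadingly small.

Chain comparison pairs each genome with the next in the listed order and
reports the pair on the first genome's row, leaving the final row empty —
the layout used by multi-taxon report tables.  The full pairwise matrix
(`compare_all_pairs`) is provided as the obvious generalization.

Reconstructions of published comparison values use centers and geometric
means printed at 2 decimals as inputs, so agreement is asserted to the
rounding tolerance of those inputs: 0.05 absolute on Gm/Ed/Dr and 0.5 on
the WDr products, which amplify input rounding.

## Visualization

The primary map is the 3D trajectory; the secondary maps are the six 2D
projections in fixed order x~y, x~z, y~z, x~n, y~n, z~n; the universal map
overlays any number of tracks in one autoscaled 3D scene, colored and
legended by a TGCC manifest grouping (strain, component type, or
category).  Tracks are decimated before plotting — every stride-th point,
first and last always kept — with the default stride chosen to cap 10⁵
points per track, a memory/fidelity compromise for multi-Mbp replicons.
SVG is the default output: text is kept as text and hash salts and
timestamps are pinned, so repeated runs produce byte-identical files
(asserted in the suite).  Plotting never mutates its input track.

## Synthetic data

The generators produce (a) the 40-bp worked-example circle, whose 4×
repeat structure collapses the track to 10 distinct points and whose
center (0, 8.2, −4.1) follows from the closed form; (b) i.i.d. random
sequences with controlled base composition, seeded and bit-reproducible;
(c) rotations (cutting-point changes) and linear slices.  I.i.d.
composition is all the quantitative layer can see — the center depends on
composition alone — but it does **not** emulate the repeat structure, GC
skew, or coding organization of real genomes, so passing tests demonstrate
the transform's algebraic properties and the pipeline's correctness, not
biological discrimination power on real taxa.  Sizes used in the suite
(≤ 2 kb for the quadratic oracle, 100 kb for the throughput demo, 50 kb
for the README comparison) were chosen as the smallest scales at which
each property is meaningfully exercised.

## Degenerate inputs and tie-breaks

Empty sequences and empty tracks are rejected before any file is created;
out-of-range positions raise with the offending value; a comparison of a
single summary in chain mode is an error.  Dr of two zero geometric means
is undefined, not zero.  Decimation with stride exceeding the track length
keeps exactly the first and last points.

## Known limitations

The method compares genomes through composition-dominated summary
statistics; two sequences with identical base composition share a
geometric center regardless of arrangement (the track shapes, not the
centers, differ).  No inferential statistics are provided — the rates are
descriptive, and no universal taxonomic boundary on Dr exists.  GenBank
parsing, accession downloading and interactive rendering are out of scope.
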