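# Methods

Definitions and formulas implemented by `onhrel`. All axial/lateral positions
are in micrometres (μm); areas are in mm²; pixel coordinates convert through
per-image scales (`axial_scale`, `lateral_scale`, μm per pixel) that are
mandatory metadata — missing or invalid scales are an error, never a default.

## Boundaries and interpolation

A segmentation of one B-scan consists of three control-point sets: the ILM and
the two BM wings (`BM_left`, `BM_right`) flanking the optic nerve canal.
Control points have strictly increasing column positions; each boundary needs
at least two. Between control points the boundary is the **monotone
shape-preserving piecewise cubic** (PCHIP, Fritsch–Carlson derivatives): it
passes through every control point exactly, never overshoots the interval
spanned by two neighbouring points, and preserves local monotonicity. Editing
one control point affects the curve only between its next-nearest neighbours
(`[x_{i-2}, x_{i+2}]`; the derivative at each immediate neighbour depends on
the moved point, which is what extends the influence one segment past it).

## BM bridging and cross-sectional area

BM is shadowed under the nerve head, so the measured lower boundary is the BM
wings joined by a **straight line between the two medial margins** (the last
control point of the left wing and the first of the right wing).

The cross-sectional area is the integral of `y_BM_bridged(x) − y_ILM(x)` over
a fixed lateral window of half-width `w = 2.85 mm` (total 5.7 mm) centred on
the scan's lateral midpoint, evaluated with the trapezoidal rule on a uniform
grid (default step 5 μm) and reported in mm². Depth increases downward, so a
nerve head elevated toward the vitreous decreases `y_ILM` and increases the
area. The integrand is kept signed; boundaries that cross inside the window
trigger a warning rather than silent clipping. Useful consequences, used as
test invariants: shifting both boundaries by a common depth offset leaves the
area unchanged, and shifting only the BM by δ changes the area by exactly
`2·w·δ`.

## Boundary disagreement

The difference between two segmentations of the same scan, per boundary, is
the **mean absolute vertical distance** between the two interpolated curves,
sampled on a uniform grid over the intersection of their lateral supports
(BM compared after bridging), reported in μm and in axial pixels
(px = μm / axial_scale). Comparisons are classified as intra-rater (same
rater, different sessions), inter-rater (different raters, same session) or
inter-device.

## Reliability statistics

**Limits of agreement.** For differences `d_1 … d_n` (n ≥ 2): mean ± 1.96·SD
with the sample SD (ddof = 1). Outlier flagging marks records strictly above
the upper limit (one-sided: the differences here are magnitudes).

**ICC(A,1).** Two-way random-effects, absolute-agreement, single-measurement
intraclass correlation. From the two-way ANOVA mean squares of an n × k
complete table (subjects × measurers) — MSR (rows), MSC (columns), MSE
(residual):

```
ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))
```

The average-measure variant ICC(A,k) is also provided. A table with zero total
variance has no defined ICC and is reported as undefined rather than 1.0 or 0.
An identical-column integer table yields exactly 1.0. In the pipeline, ICC
strata with subjects missing a cell (e.g. quality-excluded segmentations) are
analysed complete-case, with the dropped count noted.

**Bland–Altman.** For paired measurements (a, b): bias = mean(a − b) with its
95% CI `bias ± t_{0.975, n−1} · SD/√n`, limits of agreement as above, and the
approximate 95% CI of each limit, `limit ± t_{0.975, n−1} · SD · √(3/n)`.

## Study design and stratification

A study is a manifest CSV with one row per segmentation (scan, subject, eye,
device, protocol, rater, session, quality, paths). Rows whose `quality` is not
`pass` are excluded and logged. Summaries are always stratified by scan
protocol (line vs radial star pattern): scans of different protocols are never
pooled, and **inter-device comparisons are computed for the radial protocol
only**, because line-scan positioning varies too much between devices for the
same cross-section to be compared. The runner emits per-segmentation areas,
all pairwise boundary and area differences, limits of agreement with outlier
flags per (protocol, comparison, boundary), ICC blocks per stratum, and
Bland–Altman summaries per measurer pair.

## Synthetic phantoms

Ground truth is a parametric geometry with a closed-form area: a flat BM at
depth `b` with a central gap, and an ILM at
`y(x) = h − A·exp(−(x−c)²/(2σ²))` (A = 0 for a non-swollen nerve). With the BM
bridged flat, the window area is

```
(b − h)·2w + A·σ·√(2π)·erf(w / (σ√2))      (μm², divided by 10⁶ for mm²)
```

which serves as an exact oracle for the numerical integrator.

Simulated raters place control points on the true boundaries with (i) locally
coherent session noise — a fresh Gaussian offset per ~800 μm lateral block
with pointwise SD `axial_noise_sd`, since hand-traced errors are smooth, not
independent per click; (ii) persistent per-(rater, scan) biases shared across
that rater's sessions, which is what separates inter-rater from intra-rater
disagreement; (iii) lateral noise on the BM medial margins; and optionally
(iv) a gross ILM confusion offset. Simulated devices render intensity images
on their own pixel grids and apply a systematic axial offset (provably
area-neutral) plus small axial/lateral scale calibration errors, which do
perturb areas and drive inter-device disagreement. All randomness derives from
one study seed through hashed per-entity sub-seeds, so datasets are
byte-reproducible.
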