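# Methods

## Model

The package treats an LC-UV assay as three linked linear structures.

**Detector response.** Each component's integrated peak area is affine in
the injected mass, `A = k·m + b`, with per-(component, system) constants.
Intercepts are retained in calibration and in external-standard
inversion; they are interpreted as systematic error and deliberately
discarded by the slope-method QAMS route, which is why `QAMS2 − ESM`
equals the constant `b_i/k_i` (scaled to content units) for every sample
of one component and system. Wavelength switching during the run is not
modelled: whatever wavelength a component is detected at is absorbed
into its response slope.

**Relative correction factors.** The multipoint estimator
`f_s/i = (m_s·A_i)/(m_i·A_s)` is computed per standard level from
same-injection pairs and averaged; the slope estimator is `k_i/k_s`.
Under a proportional response (`b = 0`) they coincide identically at
every level — a property the test suite asserts to 1e-12 on simulated
data — and with non-zero intercepts the multipoint values drift with
level, which the per-level RSD quantifies. Dispersion statistics use the
sample standard deviation (n−1) throughout, the analytical-chemistry
convention; report display rounds half-up to three decimals.

**Retention.** Only the relative structure is method-defined: each
analyte carries a fixed ratio `RRT_i = rt_i/rt_s` to the
internal-reference peak. No retention physics (gradient/LSS model) is
attempted; absolute reference retention times are free parameters of the
simulation, set to 12 min (UPLC) and 30 min (HPLC) so that all five
peaks elute inside the respective gradient windows.

## Peak assignment

Unknown peaks are matched by RRT inside a fractional tolerance,
default ±2 %. The default sits between the observed cross-system RRT
scatter of the later-eluting analytes (RSD ≈ 0.2–1 %) and the smallest
inter-component RRT gap (≥ 9 %); the earliest peak's cross-instrument
spread (RSD ≈ 5 %) means a single pooled expectation is least reliable
for it, and callers comparing instrument classes may prefer
system-specific expected values. When no retention-time hint is given,
the internal-reference peak is chosen as the candidate that explains the
most expected components within tolerance (unit penalty per unexplained
component, ties broken by summed deviation); with a hint, the
largest-area peak inside the hint window wins. Two peaks inside one
component's window raise an ambiguity error rather than guessing;
components with no matching peak are reported absent.

## Synthetic data

The generator emulates the study design the analysis assumes: a mixed
working standard (245.2 / 108.0 / 416.0 / 46.0 / 72.2 µg/mL of C1–C5)
injected at six volumes per system (0.2–1.0 µL UPLC, 2–10 µL HPLC,
spanning each published linear range), and ten regional leaf samples
extracted at 4.0 g powder per 20 mL, injected in triplicate. Defaults
for response constants, contents and RRTs are the published longan-leaf
values in `qams.longan`.

Noise is multiplicative normal on areas (sd = RSD·mean, truncated at
zero — detector counts cannot go negative), with per-component default
RSDs at the published instrument-precision levels (0.17–0.38 % UPLC,
0.65–1.98 % HPLC). Retention noise is split into a *common-mode*
multiplicative drift per injection (default 0.3 %) — flow and
temperature fluctuations move the whole chromatogram together, and this
part cancels exactly in RRTs, which is the empirical basis of RRT peak
location — plus small independent per-peak jitter (default 0.02 min
UPLC / 0.05 min HPLC) representing apex determination. Heavier-tailed
noise, peak tailing (EMG shapes), co-elution, carryover and detector
saturation are not modelled; passing tests therefore demonstrate the
*statistical* machinery, not robustness to pathological chromatography.

Rendered chromatograms are sums of Gaussians whose integrals equal the
peak areas, over an optional linear baseline with white noise; the
companion integrator detects apexes by prominence, bounds each peak at
the valleys towards neighbouring apexes, and subtracts a local linear
baseline under trapezoidal integration. Rendering requires at least 10
samples per peak standard deviation; on well-separated peaks the
round trip recovers areas within 0.5 %.

## Method transfer

Between columns, flow scales with cross-section (`ν·d²` constant linear
velocity), injection volume with geometric column volume (`d²·L`), and
gradient breakpoint times with column volume over flow (constant
gradient volume in column volumes); %A values are untouched. Porosity
and dwell volume are ignored — both cancel or are out of scope for
ratio-based scaling — so transferred conditions are starting points, as
in pharmacopoeial practice, not guarantees of identical selectivity.
Transfers compose and invert exactly (A→B→A is the identity to machine
precision).

## Numerical and design choices

- Calibration is ordinary least squares with a free intercept
  (`scipy.stats.linregress`); reported `r` is the Pearson correlation of
  (mass, area). The linearity gate defaults to r ≥ 0.9996, the level
  every published curve reaches. No weighting, no LOD/LOQ.
- External-standard inversion flags, but does not reject, masses outside
  the validated linear range, including negative masses when a peak area
  falls below a positive intercept; negative contents are reported with
  a `below_zero` flag for transparency near the detection limit.
- QAMS1's working equation `m_i = (m_s·A_i)/(f·A_s)` is the unique
  rearrangement of the multipoint definition with `m_s` taken from the
  internal reference's own calibration curve — the one route consistent
  with calibrating only the reference.
- Replicate injections (`n = 3` by default, matching the reporting
  convention of the content tables) are averaged per base sample after
  conversion to content.
- Peak tables are a fixed CSV dialect (UTF-8, comma, `.` decimal,
  floats written with `repr`) so write→read is bit-exact; an absent
  injected mass is an empty cell, distinct from a 0 µg blank.
- All simulation randomness flows through `numpy.random.default_rng`
  seeds; identical seed and parameters give bit-identical tables.

## Problem sizes

The bundled study conditions are small by design: 6 calibration levels ×
5 components × 2 systems, 10 regions × 3 replicates, 9-portion spike
studies, and 100–1000-replicate stochastic harnesses; the full test
suite and the reproduction script each run in seconds.

## Known limitations

- The HPLC column geometry bundled with the default systems is nominal
  (4.6 mm × 212 mm chosen to reproduce the published 5× flow and ~10×
  injection scaling); transfer results depend on user-supplied geometry.
- Cross-instrument content correlations are computed on the published
  per-region means; the underlying replicate-level data are not
  available, so those correlations inherit the tables' rounding.
- Assignment assumes one peak per component; fused or split peaks must
  be resolved upstream (the integrator does no deconvolution).
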