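# Methods

## Scope and data model

`lcmsqc` operates on centroided MS1 spectra from mzML files. The
canonical retention-time unit is minutes everywhere; scan times stored
in seconds are converted on read. Runs are identified by a SHA-1 of
file content, not path, so moved or renamed files are recognized as
already processed. Profile-mode data is accepted and processed as-is
with a logged warning: all downstream operations treat peaks as
centroid sticks. MS2 scans are read but ignored by every monitoring
module.

The mzML reader is deliberately narrow (base64-encoded 32/64-bit float
arrays, zlib or no compression, plain or gzip files) and is validated
in the test suite against Bioconductor's mzR, an independent
ProteoWizard-based reader, on generated files.

## Extracted-ion chromatograms

An EIC for target m/z *m* with tolerance *t* ppm collects, per MS1
scan, all centroids in the half-open window [m·(1−t·10⁻⁶), m·(1+t·10⁻⁶));
the half-open upper bound makes window membership deterministic at the
boundary. Scan intensity is the sum over in-window centroids; the
per-scan observed m/z is their intensity-weighted mean (undefined where
the scan has no in-window signal). Every MS1 scan contributes a point,
zero-filled — this is what makes the contaminant mean meaningful. The
default tolerance is ±20 ppm, shared between compound tracking and
contaminant screening with per-call overrides. Note that the window
must be wider than the calibration error one intends to *measure*: a
drift survey spanning ±30 ppm needs a ±50 ppm window, which is how the
acceptance measurements are configured.

## Peak location and metrics

Tracked compounds have known expected RTs, so peak location is a
windowed argmax within ±0.5 min (default) of the expected RT — not a
general peak picker. Interbatch drifts in practice are on the order of
0.1 min, so 0.5 min gives headroom; it is configurable per call. Ties
are broken by proximity to the expected RT, then by the earlier scan.
A detection requires the apex to exceed a configurable absolute
threshold (default 0) and to sit inside a run of at least 3 consecutive
non-zero scans, which rejects single-spike noise.

Integration bounds extend from the apex in both directions while the
signal keeps falling and stays above 1 % of the apex, stopping at the
first local minimum or the floor, whichever comes first. The peak area
is the trapezoidal integral of the EIC over these bounds; the observed
m/z is the EIC-intensity-weighted mean of per-scan m/z values over the
same bounds. Weighting across the peak (rather than taking the apex
scan alone) averages centroid-level mass jitter; this is a deliberate
choice where either convention is defensible.

## Peak-shape factors

The shape diagnostics follow the pharmacopeial definitions: the USP
tailing factor W₀.₀₅/(2f) at 5 % of apex height, and the asymmetry
factor b/a at 10 % height. Crossing points on each side of the apex are
located by linear interpolation between the bracketing scans. When a
crossing is not bracketed inside the chromatogram (truncated peak, apex
on the boundary), both factors are null with a machine-readable reason
rather than an extrapolated number. Accuracy is sampling-limited: on a
grid with spacing Δ the apex position is known only to ±Δ/2, so the
factors of a σ = 0.1 min peak agree with a dense-grid evaluation to
within 1 % once Δ ≲ σ/60. Tests and acceptance measurements therefore
use densely sampled fixtures for shape assertions.

## Contaminant screening

Each listed ion gets a full-run EIC summarized as max and mean. The
mean's denominator is the total MS1 scan count including zero-filled
scans — a contaminant present in 1 of 100 scans averages to 1 % of its
height while a constant trace keeps its full level, which is exactly
the discrimination between transient and pervasive contamination the
two summaries exist to provide. The bundled list (235 ions) is computed
from monoisotopic masses for the homologous series (PEG, PPG, cyclic
siloxanes, sodium formate/acetate clusters, solvent clusters) plus
well-known single background ions; it is data, not code, and any
user CSV replaces it.

## Storage, scheduling, warnings

The store is a single-file SQLite database with a migrations table;
timestamps are stored as UTC ISO-8601. Scheduling is idempotent by a
(file, module) uniqueness constraint, metric inserts by (file,
compound) and (file, contaminant, m/z): reprocessing an unchanged
directory adds zero rows anywhere. Failed schedule entries are
re-queued until a retry limit (default 3).

Warning rules use strict inequality ("exceeds"), and `abs_gt` is the
natural comparator for signed deviations. Events deduplicate per
(rule, file, metric, target) in the store. Sinks (log, webhook, SMTP)
are failure-isolated: a dead mail host yields a `delivered=false` entry
in the delivery report and a log line, never an aborted pipeline.

## Reporting

The five analytical views are rendered as static HTML with CSV tables
and PNG figures. Heatmap rows are hierarchically clustered with
correlation distance and average linkage on log10(1+x)-transformed
intensities; intensities span orders of magnitude, and correlation on
the log scale groups ions whose *temporal pattern* matches regardless
of absolute level — the grouping that points at a common source. Rows
are canonically name-sorted before clustering, which makes the leaf
order invariant under input row permutation; flat (zero-variance) rows
are assigned distance 0 to identical rows and 1 otherwise, since
correlation is undefined for them. The metric/linkage choice is a
design decision where reasonable alternatives exist (Euclidean, Ward);
it is isolated in one function.

## Synthetic batches

The generator emulates the phenomena the monitor is built to catch:
per-run ppm calibration offsets, per-run RT shifts, per-injection
multiplicative intensity decay, Gaussian and exponentially-modified
Gaussian (EMG) peaks, constant/peak/single-scan-spike contaminant
profiles with per-run activity windows, and noise centroids at uniform
random m/z with exponential intensities. The EMG is evaluated through
the scaled complementary error function (erfcx) for numerical
stability and normalized to unit apex height on a dense grid, so
configured heights are apex intensities. Default conditions are a
10-run sequence of 50 scans at 3 s spacing with three compounds
spanning m/z 180–524 and heights 10⁵–3·10⁵ counts — a small but
realistic QC injection series.

What the generator does *not* emulate: isotope patterns, adducts,
co-eluting isomers, matrix ion suppression, profile-mode peak shapes,
or mass-dependent calibration curves (the ppm offset is uniform across
m/z within a run). Passing tests therefore demonstrate correct metric
arithmetic, windowing, persistence and alerting semantics on idealized
centroid data — not robustness to the full complexity of biological
matrices.

## Determinism and problem sizes

All randomness flows from a single integer seed via numpy's
SeedSequence; identical seeds give byte-identical manifests and mzML
files. Tests and the acceptance script use batches of 10–20 runs of 50
scans, sizes at which every measured recovery is already tight
(sub-ppm mass recovery, RT recovery within half a scan interval) while
the whole suite runs in seconds.
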