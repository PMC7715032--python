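# Methods

`ca3net` models the rat entorhinal-dentate-CA3 circuit as three flattened
2D sheets, generates the excitatory connectome from anatomical
constraints, integrates reduced-compartment conductance-based neurons,
and characterizes the population activity with 3D space-time correlation
maps. This note records the model, its assumptions, the defaults, and
the choices made where the design was genuinely open.

## Geometry

Each subfield is an unfolded rectangular sheet: the longitudinal
(septotemporal) axis runs 0 mm (temporal pole) to L mm (septal pole),
the transverse (proximodistal) axis 0 (proximal, at the dentate border)
to T mm (distal). Defaults: EC 10 x 3 mm, DG 10 x 2 mm, CA3 10 x 3 mm.
The longitudinal extent matches the septotemporal length of the rat
hippocampus; the transverse extents are assumptions (no flattened-sheet
dimensions are published for this model family) and are configurable.
Full-scale populations are 112,000 EC, 120,000 DG, and 25,000 CA3
neurons placed uniformly at random (a density-profile hook exists).
Each granule cell is labeled supra- or infrapyramidal with a 0.5/0.5
split (configurable; the true split is not modelled).

CA3 is partitioned into a 3x3 section grid: transverse thirds CA3c /
CA3b / CA3a (half-open intervals, lower edge inclusive, so a boundary
position belongs to the distal column) and three overlapping
longitudinal windows centered at 7.5 (septal), 5.0, and 2.5 mm
(temporal) extending +-2.5 mm. Longitudinal window membership is closed
(|center - y| <= half-width): the windows overlap by design, and the
midpoint 5.0 mm belongs to all three.

## Spike sources

Entorhinal cells (and the "random mossy fiber" dentate surrogate) are
renewal processes: a homogeneous Poisson process whose hazard recovers
exponentially after each spike, lambda(t) = lambda0 (1 - exp(-(t -
t_last)/tau)) with tau = 35 ms. The paper family states realized rates
(5 Hz EC, 0.62 Hz DG surrogate); lambda0 is calibrated by root-finding
on the semi-analytic mean of the ISI density so the *realized* rate hits
the target. Sampling is by exact thinning from the dominating rate
lambda0. Per-neuron substreams are seeded by (seed, neuron id), so
rasters are reproducible regardless of generation order.

Binning uses half-open 1 ms bins clipped to binary values; mean and
standard deviation of each binary train are computed over all bins.

## Connectivity

*Perforant path.* Each EC cell is labeled lateral or medial (0.5
fraction). Its axon terminal field over CA3 (or DG) is a Gaussian along
the longitudinal axis, centered at the position given by the
entorhinal topographic map - the identity on the normalized
longitudinal coordinate by default, since the quantitative map is
published elsewhere - and uniform across the transverse span. The
reported 1-1.5 mm field extent is read as a +-2 sd span: sd =
extent/4, default extent 1.25 mm. In-degrees come from the layer
budget table: count = round(density x dendritic length), with layer
lengths interpolated linearly between the proximal values (0 for both
lacunosum layers) and the distal maxima (1,658 LEC / 1,105 MEC).
Presynaptic partners are drawn with replacement from the field-weighted
candidate distribution until the budget is met; repeats model
multi-synapse contacts. Delays assume axons enter at the proximal edge
at their mapped longitudinal level: path length = Euclidean distance
from (mapped level, transverse 0) to the postsynaptic position, at
0.32 m/s.

*Mossy fibers.* Each granule cell sends one fiber entering CA3 at its
longitudinal level and crossing the transverse axis, with a cubic-spline
longitudinal deviation that is zero through CA3c/CA3b and turns toward
the temporal pole within CA3a (default terminal deviation -1.5 mm;
vertex-wise Gaussian jitter, sd 0.05 mm; clipped to the sheet).
Synapses are placed by an inhomogeneous Poisson process along arc
length with region-dependent mean spacing (162 / 223 / 345 um in
CA3c/b/a, region decided by the synapse's transverse coordinate). Each
synapse captures one CA3 cell drawn uniformly among cells within 30 um,
else it is dropped (count logged). Infrapyramidal-origin fibers contact
the proximal stratum oriens while in CA3c and stratum lucidum beyond;
suprapyramidal fibers contact lucidum throughout. Delay = arc length
from the CA3 entry point to the synapse at 0.27 m/s (the short hilar
segment is neglected; in the folded anatomy granule somata abut CA3c).

*Associational system.* Each CA3 cell's axon field is a 2D skew
Gaussian (product of two 1D skew-normal densities, f(z) = 2 phi(z)
Phi(alpha z) per axis). Field parameters are interpolated bilinearly
(extrapolated linearly) from a 3x3 injection grid over (septal, middle,
temporal) x (CA3c, CA3b, CA3a). The shipped grid parameters are
placeholders qualitatively matching the anterograde-tracing literature
(fields elongated longitudinally, skewed away from the nearer pole and
toward the opposite transverse border); the fitted values are not
published. Radiatum and oriens budgets are drawn postsynaptically like
the perforant path (total 18k-29k per cell, rising distally). Delay =
Euclidean pairwise distance at 0.39 m/s. Self-connections are excluded.

*Compartment mapping.* One target compartment per (pathway, layer):
LPP -> lacunosum_distal, MPP -> lacunosum_proximal, associational
radiatum -> radiatum_proximal, associational oriens -> oriens_distal,
mossy fibers -> lucidum (or oriens_proximal for infrapyramidal fibers
in CA3c). Keeping one pathway per compartment makes per-compartment
synapse kinetics well-defined.

## Neurons

Cells are chains of eight compartments (one per input layer plus the
soma) with Hodgkin-Huxley-style channels: fast Na and delayed-rectifier
K at the soma, high-threshold Ca with fast Ca-activated K and a slow
AHP conductance in the dendrites (bursting preset), and an M-type slow
K current for adaptation. Kinetics follow the classical reduced
hippocampal formulation (rate functions written relative to a -60 mV
resting frame). Three CA3 presets reproduce the qualitative firing
taxonomy - bursting, strongly adapting, weakly adapting - under a
standard protocol (1 s somatic step at 1.25x rheobase; bursting = three
onset spikes with ISIs < 10 ms, otherwise the adaptation index
(ISI_last - ISI_first)/(ISI_last + ISI_first) > 0.3 separates strongly
from weakly adapting). The adapting presets use the standard specific
capacitance of 1 uF/cm^2 (membrane time constant 10 ms); the bursting
preset uses 3 uF/cm^2, the value its somatodendritic ping-pong loop was
tuned with. A granule preset (smaller, higher input resistance,
resting at -70 mV) reuses the same machinery for the dentate.
Quantitative trace matching to the original detailed models is not
claimed; their channel parameter tables are not available.

Network experiments default to the strongly adapting preset: adaptation
dominates CA3 pyramidal phenotypes, and it keeps the gain of the
recurrent associational loop bounded at reduced scale (the weakly
adapting preset's steep f-I curve drives the reduced recurrent network
into saturation at associational strengths where the full-scale system
stays moderate).

Integration is semi-implicit at dt = 0.025 ms: gates advance by forward
Euler at the current voltage, then the eight-compartment voltage system
is solved implicitly (Thomas algorithm) with channel and synaptic
conductances linear in v over the step. Synaptic conductances are sums
of exponentials updated analytically; presynaptic spikes deposit
normalized weight increments into a per-arrival-step ring buffer, so
conduction delays are exact to one step. Spikes are upward somatic
crossings of -10 mV with a 2 ms lockout. Simulations are bit-exactly
deterministic given connectome, sources, and configuration.

## Synapses and calibration

AMPA conductance: peak-normalized double exponential, g(t) = w
(exp(-t/tau2) - exp(-t/tau1)), tau2 > tau1, with the analytic peak at
t* = tau1 tau2/(tau2 - tau1) ln(tau2/tau1). NMDA: peak-normalized
triple exponential w3 exp(-t/tau3) + (1 - w3) exp(-t/tau2) -
exp(-t/tau1) (normalizer found by bracketed root-finding on the
derivative), multiplied by the magnesium block 1/(1 + exp(-0.062 v)
[Mg]/3.57), [Mg] = 1 mM. NMDA time constants (5/50/150 ms, w3 = 0.5)
are assumptions; the NMDA:AMPA peak-conductance ratio defaults to 0.1.
At a ratio of 1 the slow NMDA tail would dominate the half-height width
of small EPSPs and make the narrowest target (38 ms) unreachable on
this cell; at 0.1 the NMDA contribution at rest is a small slow tail,
as observed for unitary EPSPs.

Weights and AMPA decay constants are calibrated per pathway/layer
against unitary somatic EPSP targets (peak, half-height width): 0.30 mV
and 46.1/46.1/40.9/38.0 ms for the perforant-path and associational
layers, 3.2 mV / 135 ms for mossy fibers. Stage 1 bisects tau2 against
the HHW (the HHW(tau2) curve is U-shaped because of the NMDA tail, so a
geometric grid scan locates the rising branch first); stage 2 bisects
the weight against the peak; both stages run twice, the second pass
probing at the calibrated weight to absorb the mild nonlinearity of
large EPSPs. The rise constant is slaved as tau1 = tau2/5 but capped
at 3 ms - AMPA rise times are millisecond-scale even for synapses
whose somatic EPSPs are very broad, and an uncapped ratio would give
the mossy-fiber synapse a ~30 ms rise. Calibration is performed at
rest (-65 mV) with one presynaptic event after settling; the round
trip reproduces all six targets within 0.3%.

## Correlation maps

The pairwise statistic is the overlap-normalized cross-correlation of
1 ms binary trains with mu and sigma over the full trains and
normalization 1/L(n), L(n) = N - |n| (the overlap length at shift n -
the only reading of the normalization under which the autocorrelation
equals 1 at zero lag). Pairs of distinct active neurons enter in both
orders; the signed displacement (second minus first) is floor-binned at
0.1 mm and the correlation added to every 1 ms time-lag bin, then bin
sums are divided by pair counts. Silent (zero-variance) neurons are
dropped with a logged count. Local maps admit only pairs with at least
one member inside the section. Cross-sections (longitudinal-temporal at
a transverse lag, longitudinal-transverse at a time lag) support the
30%-of-maximum threshold view. The map peak is the maximum bin value;
an optional minimum pair count per spatial bin (default 1) masks bins
whose mean rests on too few pairs to be a meaningful extreme-value
candidate on small populations. Full pair enumeration is the default
below 2,000 active neurons, with seeded uniform pair subsampling above.
The default maximum time lag is +-500 ms (configurable; analyses here
use +-100-200 ms, where all observed structure lives).

## Synthetic fixtures

Cluster rasters plant known structure: background refractory-renewal
spikes plus, for each cluster event (Poisson in time per cluster), one
extra spike for each neuron recruited with probability participation x
exp(-d^2/(2 sd^2)) at the event time plus Gaussian jitter. Ground
truth (event times, centers, participant counts) ships with every
raster. For events of spatial sd s the pair correlation falls off as
exp(-d^2/(4 s^2)), so the map's half-width at half maximum is
2 s sqrt(ln 2); the estimator inverts this after averaging the map over
near-zero transverse lags and subtracting the far-field baseline.
Fixtures exercise the full correlation pipeline - including section
logic - with no simulation dependency. What they do not emulate:
refractory interactions between background and cluster spikes, rate
heterogeneity, and the broad, weak events of the simulated dentate.

## Scale-down policy

Desk-scale experiments run all populations at a common fraction
(default 2%) on full-size sheets. Because pre- and postsynaptic
populations shrink together, per-cell in-degree budgets are kept at
their full-scale values (sampling with replacement over fewer
candidates); per-cell drive is preserved without any weight
compensation, at the cost of inflated input sharing - pairwise
correlations at 2% are much larger than full-scale values, so only
directions and orderings are meaningful, not magnitudes. The
mossy-fiber capture radius is enlarged to 30/sqrt(scale) um so the
expected number of candidate cells per synapse is unchanged.

Because the reduced cells are not parameter-identical to the original
models, per-pathway drive gains hold the reduced network at reported
operating points: the perforant-path->granule gain is bisected until
granule output is 0.62 Hz; the perforant-path->CA3 gain targets a
sparse (~2 Hz) perforant-only regime; the mossy-fiber gain targets the
~11 Hz combined perforant + dentate regime when the perforant path is
present. Mossy-fiber-only analyses use the conditional-detonator
operating point: the largest gain at which a single input at 5x
strength stays subthreshold, so single events depolarize and
coincidences fire. Gains are calibrated once per (scale, seed) on
short trial simulations of a population subset and shared across model
configurations.

## Known limitations

- No inhibitory interneurons (matching the modelled circuit, which is
  comparable to a GABA-A-blocked CA3).
- The associational parameter grid is a qualitative placeholder; the
  fitted tracer values are unpublished.
- The entorhinal topographic map is the identity on normalized
  coordinates; the measured map lives in prior literature.
- Full-scale simulation (25,000 CA3 cells, hours on a cluster) is out
  of scope; quantitative full-scale observables (absolute peak
  correlations, the 11->70 Hz associational rate curve) are not
  reproduced, only their directions at reduced scale.
- The mossy-fiber in-degree distribution depends on the assumed sheet
  geometry; with the default 10 x 3 mm CA3 sheet the full-scale modal
  in-degree is ~55-60 with ~17 synapses per fiber (the anatomical
  literature puts terminals per fiber at 11-18).
- The dentate-to-CA3 pattern lag at desk scale is ~15-25 ms:
  conduction (~6 ms median) plus threshold-crossing latency of the
  reduced cells (~10-20 ms, set by membrane dynamics that are not
  matched to the original models). The direction (CA3 follows the
  dentate by a positive lag of order ten milliseconds) is robust.
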