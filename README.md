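# ca3net

A simulator and analysis toolkit for studying how the topographic
organization of excitatory afferents shapes the spatiotemporal
correlation structure of population activity in rat hippocampal CA3.

The hippocampal CA3 subfield receives three excitatory projections with
very different anatomy: the entorhinal **perforant path** (lateral and
medial divisions, Gaussian terminal fields organized along the
septotemporal axis), the dentate **mossy fibers** (single thin fibers
crossing the transverse axis with sparse, very strong "detonator"
synapses), and the massive recurrent **associational** system
(skew-Gaussian axon fields, 18,000-29,000 inputs per cell). `ca3net`
generates anatomically constrained stochastic connectomes for this
circuit on unfolded 2D sheets, simulates reduced eight-compartment
conductance-based neurons with EPSP-calibrated AMPA/NMDA synapses, and
quantifies the resulting activity with **3D space-time correlation
maps**: the average of overlap-normalized pairwise spike
cross-correlations

    (x*y)[n] = 1/(sigma_x sigma_y) * 1/L(n) * sum_m (x[m]-mu_x)(y[m+n]-mu_y)

indexed by each pair's longitudinal lag, transverse lag (0.1 mm bins)
and time lag (1 ms bins), globally or restricted to nine CA3 sections
(CA3c/b/a x septal/middle/temporal). It is aimed at computational
neuroscientists studying correlation propagation through the
entorhinal-dentate-CA3 circuit at configurable scale.

See `docs/methods.md` for the model details, defaults, and limitations.

## Worked example

Calibrate the unitary mossy-fiber synapse against its experimental
somatic EPSP constraints and measure the result:

```python
from ca3net.simulate import reference_cell
from ca3net.synapses import calibrate_synapse, measure_epsp

cell = reference_cell()                      # reduced CA3 pyramidal cell
cal = calibrate_synapse(cell, "lucidum", 3.2, 135.0)
m = measure_epsp(cell.epsp_trace("lucidum", cal.ampa, cal.nmda))
print(f"peak {m.peak_mV:.2f} mV, HHW {m.hhw_ms:.1f} ms, "
      f"tau2 {cal.ampa.tau2:.0f} ms, weight {cal.ampa.weight*1e3:.2f} nS")
```

```
peak 3.20 mV, HHW 135.1 ms, tau2 157 ms, weight 2.77 nS
```

The calibrated synapse reproduces the 3.2 mV / 135 ms unitary
mossy-fiber EPSP at the soma; the fitted decay constant and peak
conductance are what the network simulations then use. The same
procedure covers all six pathway/layer targets (perforant path and
associational layers at 0.30 mV with 38-46 ms half-height widths).

Generate a small network and its correlation map from the shell:

```bash
ca3net build-connectome --scale 0.02 --seed 1 --out conn
ca3net run-experiment --model PP-CA3 --scale 0.02 --seed 1 --outdir out/
```

The experiment bundle reports the mean CA3 rate, the global-map peak
correlation, and the nine local-map peaks, and writes all rasters and
maps as npz with a JSON summary.

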