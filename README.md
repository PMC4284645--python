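# clamptrace

Quantification of DNA-bound sliding-clamp dynamics in live *Escherichia
coli* from single-molecule fluorescence microscopy.

The β₂ sliding clamp (DnaN) is the homodimeric ring that tethers DNA
polymerase III to the template.  During replication a new clamp is loaded
at every lagging-strand primer, and clamps are unloaded slowly, so a
steady-state population of clamps accumulates on the DNA behind the
replication forks.  `clamptrace` implements the full measurement chain for
that picture:

* **kinetics** — the immigration–death model of the bound-clamp count
  `N(t)`: loading at constant rate `k_p`, per-clamp unloading with time
  constant `t_unload`, giving a Poisson plateau `N_ss = k_p·t_unload` and
  the steady-state balance `t_load = t_unload / N_ss`; fixed-step and
  exact Monte Carlo samplers plus the analytic mean.
* **synthgen** — a synthetic mother-machine microscopy generator
  (fluorescence + brightfield time-lapse, PALM movies, single-fluorophore
  calibration fields) with exact per-frame ground truth.
* **timelapse** — background subtraction, flat-fielding, fiducial drift
  correction, per-channel kymographs, cell-cycle segmentation and
  selection, and decomposition of each cell's fluorescence into
  background / cytoplasm / DNA-bound foci.
* **calibration** — single-fluorophore intensity standard, photobleaching
  correction, conversion to absolute molecule (clamp-dimer) counts, and
  population averaging on normalized replication phase.
* **palm** — à-trous wavelet spot detection, single-molecule trace
  building and single-step filtering, censored-exponential fitting of
  on-times, bleaching correction by competing exponential risks, and
  bootstrap confidence intervals (`UnloadingModel(...).fit()` →
  `UnloadingResults` with `summary()`).

See `docs/methods.md` for the model details and design choices.

## Worked example

Steady-state balance with the measured parameters — a plateau of 46
DNA-bound clamps maintained by unloading every 195 s implies one new clamp
loaded every ~4 s:

```python
>>> from clamptrace import KineticParams, steady_state_mean, effective_loading_time
>>> params = KineticParams(k_p=46/195, t_unload=195.0, t_rep=4080.0, dt=0.05)
>>> steady_state_mean(params)
46.0
>>> effective_loading_time(46, 195).t_load_eff
4.239130434782608
```

Estimating the unloading time from 84 synthetic single-molecule on-times
(5 s frames, competing bleaching with a 500 s wall-clock constant):

```python
>>> from clamptrace import OnTimeSet, UnloadingModel, sample_on_times
>>> on, censored, _ = sample_on_times(84, t_unload=195.0, t_bleach_wall=500.0,
...                                   frame_interval_s=5.0, movie_length_s=1200.0,
...                                   seed=11)
>>> s = OnTimeSet(on, 5.0, 0.4, censored, 1200.0)
>>> res = UnloadingModel(s, t_bleach_wall=500.0).fit(n_bootstrap=10_000, seed=0)
>>> print(res.summary())
Single-molecule unloading-time fit
==============================================
observations (on-times)                84
censored                                0
observed time constant t_obs        122.6 s
bleaching (wall-clock)              500.0 s
unloading time t_unload             162.4 s
95% bootstrap CI               [118.0, 217.7] s
bootstrap replicates                10000
```

The observed disappearance time constant (122.6 s here) mixes unloading
and photobleaching; subtracting the known bleaching rate yields the
unloading time, whose bootstrap interval comfortably covers the 195 s
ground truth of this draw — at n = 84 the estimate scatters by roughly
±30 s between draws.

A full synthetic experiment from the shell:

```sh
clamptrace synth --preset timelapse --out-dir tl
clamptrace analyze-timelapse --stack tl/fluorescence.tif \
    --brightfield tl/brightfield.tif --beam-profile tl/beam_profile.tif \
    --config tl/config.json --out-dir tlres
clamptrace synth --preset calibration --out-dir cal
clamptrace calibrate --fields cal/calibration.tif --out std.json
clamptrace quantify --cells tlres/cells.csv --standard std.json
```

which ends with the population summary, e.g.

```
Population replication-phase average
==============================================
cells averaged                         11
plateau window (phase)         [0.30, 0.90]
plateau mean bound count             47.6
plateau s.d. (cell-to-cell)           2.9
plateau s.e.m.                       0.87
bound fraction at mid-phase          0.59
```

i.e. on this short demo movie the pipeline recovers a plateau of ~47
DNA-bound clamp dimers (truth 46) with the majority of clamps DNA-bound at
mid-replication.

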