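# wakewatch

Tools for studying how the turbulent wake of a man-made tidal structure
creates a predictable foraging hotspot for surface-feeding seabirds (terns).
The package implements the full computational chain such a study needs, each
stage testable against seeded synthetic data with known ground truth:

* **Aerial video analysis** — moving-target detection in nadir drone footage
  (frame differencing, segmentation, size filtering), a bag-of-features
  tern-vs-foam chip classifier, and constant-velocity Kalman multi-target
  tracking with flight metrics (speed, turning, sinuosity) and a
  surface-eddy shedding-frequency estimator.
* **ADCP processing** — raw echo intensity to volume backscatter via the
  working sonar equation

  `Sv = C + 10·log10((Tx+273.16)·R²) − 10·log10(L) − P_DBW + 2αR + Kc·(E−Er)`

  with Sv_max across the four beams as a macro-turbulence proxy,
  bottom-track velocity correction, transect gridding, and wake-deficit
  extent estimation at half maximum.
* **Hurdle count model** — foraging counts per minute modelled as binomial
  presence × zero-truncated negative-binomial abundance, with site
  intercepts, per-site cyclic cubic smooths of tidal state (6 knots, 12.4 h
  period), AR1-aware inference, prediction and term-wise F-tests.
* **Particle transit** — Langevin advection–dispersion of trickle-released
  passive particles (dx = u·dt + sqrt(2·Dh·dt)·ξ) through a log-law channel
  flow with reflecting boundaries, and transit-time statistics to a
  downstream target.
* **Synthetic data** — seeded generators for all four input classes (wake
  scenes with a vortex-street signature, labelled chips, survey count
  series, ADCP wake transects, channel flows), each attaching ground truth.

## Worked example

`examples/` contains one short script per capability.  For instance, the
ADCP wake section (`python examples/03_adcp_wake_section.py`) prints:

```
201 pings across 200 m, 20 x 1 m bins
backscatter anomaly at wake centre: +9.7 dB (true +10.0 dB)
depth-averaged speed: 5.03 m/s outside the wake, 2.51 m/s at the deficit minimum
cross-stream deficit extent at half maximum: 44.9 m (true 45 m)
```

i.e. from simulated raw ensembles the sonar-equation processing recovers the
wake's +10 dB backscatter signature, the halved mid-wake current speed, and
a 45 m-wide velocity deficit — the physical footprint over which foraging
terns concentrate.  `examples/01_detect_and_track_terns.py` runs the video
chain end-to-end and prints per-track duration, speed and sinuosity;
`examples/04_hurdle_counts.py` fits the two-part count model and prints
F-tests and tidal-state predictions per site.

A thin CLI orchestrates the same stages end-to-end with per-stage seeds and
a hashed output manifest:

```bash
wakewatch run --config run.yaml --seed 1 --out runs/demo
wakewatch simulate adcp --seed 1 --out runs/adcp
```

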