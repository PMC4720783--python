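# esnet

Network conditions for explosive synchronization (ES) in multichannel EEG-like
recordings, implemented as a tested, reusable pipeline:

- **connectivity** — zero-phase band-pass filtering, 10-s epoching, weighted
  phase lag index (WPLI) estimation from Hann-tapered overlapping segments,
  proportional thresholding (top 30% of pairs by default), global WPLI.
- **topology** — degree, normalized betweenness centrality, global efficiency,
  Louvain modularity (seeded, best-of-restarts), degree assortativity over
  edge-end pairs (flagged undefined on regular graphs), hub flags, regional
  summaries over six scalp regions.
- **spectral** — per-channel Welch peak frequency inside a band (state-level
  peak = mean of per-epoch peaks), normalized frequency difference
  `Y = |f_i - f_j| / (|f_i| + |f_j|)`, and the degree–frequency Spearman
  correlation with exact/Monte-Carlo permutation significance.
- **suppression** — the anesthesia-adapted local suppressive rule
  `s_ij = Y_ij - lambda (r_i + r_j)` with `lambda = 1 - c` (rescaled
  anesthetic concentration) and `r_i` the mean WPLI over neighbors; per-node,
  per-region and global suppression strength, plus windowed timecourses with
  the dominant suppressed region per window.
- **session** — EDF / delimited-matrix recording I/O with montage and
  annotation sidecars, five-state segmentation around LOC/ROC, responsiveness
  smoothing, amplitude-based artifact flagging, and `run_full_analysis`
  producing deterministic TSV tables + a JSON manifest.
- **synth** — Kuramoto-oscillator session generator: scale-free or
  Erdos-Renyi graphs rewired to a target assortativity, Gaussian-copula
  degree-correlated natural frequencies, stochastic Heun integration, and
  rendering to multichannel recordings with 1/f background noise under an
  anesthesia-like concentration protocol.
- **es_sweep** — adiabatic forward/backward coupling sweeps, order parameter,
  jump and hysteresis detection to classify explosive vs gradual transitions.

## CLI

```bash
# synthesize a session: recording + montage + annotation + ground truth
esnet simulate --schedule "0:0,600:0.6,1800:0" --duration 2400 \
    --seed 1 --out-dir session/

# full analysis: per-state tables and windowed timecourses
esnet run --recording session/recording.tsv --montage session/montage.json \
    --annotation session/annotation.json --band alpha \
    --threshold-fraction 0.3 --seed 1 --out-dir report/

# individual stages
esnet connectivity --recording session/recording.tsv \
    --montage session/montage.json --out-dir conn/
esnet suppression --recording session/recording.tsv \
    --montage session/montage.json --annotation session/annotation.json \
    --window-sec 10 --region-rule either --out timecourse.tsv
esnet sweep --n 200 --freq-mode degree --grid 0.1:2.0:39 \
    --settle-sec 20 --seed 1 --out sweep.tsv
```

Recording input is either standard 16-bit EDF or a channels x samples
TSV/CSV with a `<file>.json` sidecar `{"rate": ..., "channel_names": [...]}`;
the montage is a JSON map from channel name to one of `prefrontal, frontal,
central, temporal, parietal, occipital`; the annotation JSON carries the
concentration schedule (rescaled to [0, 1]), the per-30-s responsiveness
trace, and LOC/ROC times.

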