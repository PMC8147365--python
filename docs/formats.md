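# File formats

All CSV files are comma-separated UTF-8 with a mandatory header row and
'.' decimals. All JSON model files carry `schema_version` (readers
reject unknown major versions) and a `kind` tag identifying the payload.

## Sensor CSV (`sensor_sim` contract)

One row per frame. Columns:

| column      | type  | meaning                                        |
|-------------|-------|------------------------------------------------|
| event_id    | int   | fall-event identifier                          |
| frame_idx   | int   | frame index within the event (0-based)         |
| t           | float | timestamp, s, strictly increasing per event    |
| u, v        | float | face-centroid image coordinates, px; empty when face_valid is False |
| d1, d2, d3  | float | the three ultrasonic ranges, cm                |
| face_valid  | bool  | face detected in this frame                    |
| r1..r3_valid| bool  | range within the sensing limits                |
| stage       | str   | ground truth: normal / transition / fall (simulation only) |

## Trajectory CSV (`fusion` contract)

One row per (windowed) trajectory point: `event_id, t, x, y, z, vx, vy,
vz, speed, stage` — x/y in px, z in cm, speeds in unit/s.

## Model JSON

* `kind: normalization` — feature names, mean vector, whitening matrix
  (shape + row-major data).
* `kind: fall_map` — projection pair, embedded 2D normalization, GMM
  parameters (weights/means/covariances), role indices, SD multiplier,
  selected K.
* `kind: hamiltonian_curve` — K values, mean Hamiltonian per K,
  selected K*, ε, stabilized flag, per-K γ.
* `kind: manifest` — config hash, seed, full config, output file list.
* `kind: evaluation_report` — pooled and per-fold counts/metrics
  (2-decimal display values alongside raw), lead-time summary, fold
  assignments. A flat single-row CSV summary is written next to it.

## Pipeline config YAML

Nested sections `sim / ddft / fallmap / eval` plus top-level `seed` and
`log_level`, mirroring the dataclasses in `fallwatch.config`; unknown
keys are rejected. `PipelineConfig().to_yaml(path)` writes a complete
default file to start from.
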