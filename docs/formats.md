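# File formats

Positions are metres in the game plane (origin at the containment-zone
centre, +y "up"); angles are degrees measured from the +y axis, clockwise
positive, in (-180, 180].

## Trajectory logs (CSV)

Long format, one row per (sample, agent), sampled at 50 Hz:

| column        | type  | meaning                                             |
|---------------|-------|-----------------------------------------------------|
| `t`           | float | sample time (s), uniform and strictly increasing    |
| `agent_id`    | str   | `HA` or `TA0`, `TA1`, ...                           |
| `role`        | str   | `HA` or `TA`                                        |
| `x`, `y`      | float | position (m)                                        |
| `heading_deg` | float | herder heading; empty for targets                   |
| `vx`, `vy`    | float | target velocity (m/s); empty for the herder, whose speed is the model constant `v0` |
| `influenced`  | bool  | target within the herder's influence radius         |
| `contained`   | bool  | target latched as corralled                         |
| `targeted_ta` | int   | id of the currently targeted TA (repeated per row)  |

Floats are written with 17 significant digits and read back with
round-trip precision, so write-then-read is lossless. Readers reject
missing columns, NaN coordinates and non-monotone time with line numbers.

## Trial configs (JSON)

```json
{
  "ha_position": [20.0, -30.0],
  "ha_heading_deg": 35.0,
  "ta_positions": [[-10.0, 25.0]],
  "arena": {"width": 120.0, "height": 90.0, "containment_radius": 4.0,
            "wall_force_magnitude": 4.0, "influence_radius": 10.0,
            "ta_stop_speed": 0.1},
  "model": {"b": 3.5, "kg": 42.5, "ko": 200.0, "c1": 0.5, "c2": 0.5,
            "c3": 0.5, "c4": 0.15, "c5": 0.5, "c6": 0.5, "c_offset": 8.5,
            "epsilon_deg": 5.0, "v0": 5.0, "zeta_gain": 1.0},
  "ta_params": {"alpha_r": 20.0, "beta": 0.2, "f_max": 30.0},
  "policy": {"name": "successive_collinear_angle",
             "collinear_threshold": 18.9},
  "dt": 0.02, "max_duration": 120.0, "policy_period": 0.25,
  "latch_mode": "entry", "policy_mode": "locked"
}
```

`policy` is omitted for single-target trials. Policy names are the
lower-snake-case catalogue names (e.g. `successive_collinear_angle`,
`furthest_from_containment_zone`).

## Score tables (CSV)

`infer-policy` writes one row per policy plus an `other` row:
`policy, excl_N, excl_P, nonexcl_N, nonexcl_P`. The optional threshold
sweep is `threshold_deg, accuracy` (plus one column per participant when
labels are available).

## Manifests (JSON)

Every CLI command writes `manifest.json` next to its outputs: the exact
command line, the seed (when one applies), a SHA-256 hash of the trial
config (for `simulate`), the output paths, the package version and a UTC
timestamp.
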