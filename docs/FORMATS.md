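# File format contract (format_version 1.0)

Every file written by the CLI carries a JSON sidecar
(`<file>.meta.json`) with `format_version`, `package_version`, and
run metadata (dt, sites, seed as applicable).  Readers accept older
minor versions and reject files from a newer *major* version.

## Voltage/current traces (CSV)

| column       | units | description                          |
|--------------|-------|--------------------------------------|
| `time_ms`    | ms    | uniform sample times                 |
| `<site>`     | mV    | one column per recorded site (e.g. `soma`, `ais_distal`, `dend`) |

HDF5 variant (optional, via h5py): `time_ms` dataset plus one dataset
per site under `/sites`, with `format_version` as a root attribute.

## Per-spike feature tables (CSV)

`threshold` (mV), `threshold_time` (ms), `ais_inflection_dvdt`,
`ais_max_dvdt`, `somatic_peak_dvdt` (V/s), `peak_v` (mV), `peak_time`
(ms), `ahp` (mV), `inst_freq` (Hz).  NaN marks an absent feature
(e.g., AIS components of a monophasic spike).

## Protocol tables (CSV)

* density sweep: `scale`, first-AP feature columns, `spike_count`,
  `last_ahp` — 11 rows (100%…0%).
* crossover sweep: `crossover_um`, `nav12_pct`, `nav16_pct`,
  `threshold`, `ais_peak`, `somatic_peak` — 80 rows.
* onboarding recovery: `time_since_offset_s`, absolute features,
  `delta_*` (recovery − baseline), `blocked_nav12`, `blocked_nav16`.
* nucleated patch: `pulse_time_s`, `phase`
  (baseline/recovery), `peak_na` (nA), `normalized_peak_current`.
* long train: `bin_s`, `delta_threshold` (mV), `delta_peak_dvdt`
  (V/s), `delta_inst_freq` (Hz), `spike_count_bin`.
* seizure: `bin_start_s`, `phase` (baseline/seizure/recovery),
  `n_spikes`, `threshold` (mV), `inst_freq` (Hz), `rate_hz`.

## Curve-fit inputs/outputs

Fit input CSVs are two-column `(x, y)`: voltage (mV) + normalized
response for Boltzmann fits; dose (nM) + normalized remaining current
for Hill fits.  Fit output is JSON: `params`, per-parameter `stderr`,
`residual_norm`, `converged`, `n_points`, `message`.

## Synthetic-data ground truth

Each generator writes `<kind>.truth.json` beside its CSV holding the
generating parameters (and derived landmark truth for AP fixtures).

## Run manifests

`<protocol>_manifest.json`: `config_hash` (sha256 of the canonical
sorted-key JSON of the configuration — stable under key reordering),
`seed`, `version`, `protocol`, `outputs`, `wall_time_s`.
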