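# walkanchor pipeline configuration.
# All values shown are the package defaults; omit any key to keep it.

epoch_short_s: 1          # base AVM epoch (s)
epoch_long_s: 15          # analysis epoch (s); must be a multiple of epoch_short_s
bout_max_rest_s: 5.0      # max rest inside one walking bout (s, inclusive)
long_walk_min_s: 60.0     # LONG walk: minimum duration (s)
long_walk_min_cadence_spm: 80.0   # LONG walk: median cadence strictly above (spm)
all_walk_min_steps: 5     # ALL walk: minimum step count
valid_day_min_wear_h: 10.0        # valid day: waking wear at least this (h)
clinical_threshold_min: 20.0      # clinically important sedentary misclassification (min)
seed: 0

cut_points:
  # PLACEHOLDER generic ENMO-style wrist thresholds (milli-g).
  # Transcribe published, population-specific cut points here before any
  # deployment; the pipeline never supplies study-specific values itself.
  light_threshold_mg: 45.0      # at/above: at least light
  moderate_threshold_mg: 100.0  # at/above: MVPA
  provenance: "generic ENMO-style defaults - replace with published older-adult wrist cut points"
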