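# Worst-case two-successive-day classroom demonstration: 30 people rubbing
# hands 3 times/day (0, 3, 6 h into each 8 h day) with 3 mL of 70% w/w
# ethanol gel (density 0.8 g/mL) in a 116 m3 room with defective mechanical
# ventilation (0.08 m3/min).
room:
  volume: 116        # m3
  vent_rate: 0.08    # m3/min
persons: 30
frictions_per_person_per_day: 3
gel_ml_per_friction: 3.0
ethanol_mass_fraction: 0.70
gel_density_g_per_ml: 0.8
event_times_day: [0.0, 3.0, 6.0]
day_starts: [0.0, 24.0]
exposure_hours_per_day: 8.0
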