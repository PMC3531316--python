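# Bell-model unfolding parameters for the FnIII domain types of a
# fibronectin monomer (15 unique types; a dimer carries two copies of each).
#
# k0_per_s   : unfolding rate at zero force [1/s].  Spontaneous FnIII
#              unfolding is rare, of the order of one event per 100 s.
# delta_x_nm : projected bond displacement at rupture [nm].
#
# Single-molecule force spectroscopy provides rate information for only a
# subset of the types; the remaining types are aliased to FnIII-12
# (alias: <name>).  The values below encode the known mechanical hierarchy
# of FnIII modules (FnIII-1 the most mechanically stable; FnIII-2, the
# third type and FnIII-9/-10 among the weakest) and are deliberately kept
# editable: replace rows with your own calibration if you have one.
#
# initially_unfolded: true marks both copies of a type as unfolded in the
# relaxed fiber (alternative to the 0/4/8 presets).
domains:
  - {name: FnIII-1, k0_per_s: 1.0e-4, delta_x_nm: 0.38}
  - {name: FnIII-2, k0_per_s: 2.0e-2, delta_x_nm: 0.40}
  - {name: T-FnIII-3, k0_per_s: 2.0e-2, delta_x_nm: 0.40}
  - {name: FnIII-4, k0_per_s: 2.0e-3, delta_x_nm: 0.40}
  - {name: FnIII-5, k0_per_s: 2.0e-3, delta_x_nm: 0.40}
  - {name: FnIII-6, alias: FnIII-12}
  - {name: FnIII-7, alias: FnIII-12}
  - {name: FnIII-8, alias: FnIII-12}
  - {name: FnIII-9, k0_per_s: 3.0e-2, delta_x_nm: 0.38}
  - {name: FnIII-10, k0_per_s: 1.0e-2, delta_x_nm: 0.38}
  - {name: FnIII-11, alias: FnIII-12}
  - {name: FnIII-12, k0_per_s: 8.0e-3, delta_x_nm: 0.40}
  - {name: FnIII-13, k0_per_s: 3.0e-3, delta_x_nm: 0.40}
  - {name: FnIII-14, alias: FnIII-12}
  - {name: FnIII-15, alias: FnIII-12}
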