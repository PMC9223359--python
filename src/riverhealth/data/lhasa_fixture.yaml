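# Published whole-river assessment values for the Lhasa River (2011-2014),
# transcribed verbatim for regression testing.  These are reference inputs,
# never recomputed in place: g/E (temporal) and f/E/T (spatial) are the
# printed quantities from which the remaining statistics can be re-derived.
subsystem_weights:
  natural: 0.67
  social: 0.33
river:
  name: Lhasa River
  main_stem_km: 551
  stations: [Pangduo, Tanggya, Lhasa]
temporal:
  years: [2011, 2012, 2013, 2014]
  g_social: {2011: 0.625, 2012: 0.637, 2013: 0.705, 2014: 0.714}
  relative: {2011: 1.034, 2012: 1.025, 2013: 0.930, 2014: 0.908}
  composite: {2011: 0.639, 2012: 0.648, 2013: 0.671, 2014: 0.668}
  development: {2011: 0.799, 2012: 0.805, 2013: 0.819, 2014: 0.817}
spatial:
  positions: [upstream, midstream, downstream]
  f_natural: {upstream: 0.664, midstream: 0.654, downstream: 0.615}
  relative: {upstream: 0.954, midstream: 1.015, downstream: 0.973}
  composite: {upstream: 0.674, midstream: 0.653, downstream: 0.630}
  development: {upstream: 0.821, midstream: 0.808, downstream: 0.794}
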