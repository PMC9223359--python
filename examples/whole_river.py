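"""Length-weighted aggregation of per-station results to the whole river.

Each station represents a river segment; whole-river natural and social
functions are the length-weighted means of the per-station values, and the
coordination statistics follow from those.
"""

import riverhealth as rh

# Per-station subsystem indices (upstream to downstream) and an equal-thirds
# split of a 551 km main stem among the three stations.
per_station = {
    "Pangduo": rh.SubsystemScores(0.664, 0.696, unit="Pangduo"),
    "Tanggya": rh.SubsystemScores(0.654, 0.644, unit="Tanggya"),
    "Lhasa": rh.SubsystemScores(0.615, 0.632, unit="Lhasa"),
}
layout = rh.ReachLayout.equal_segments(list(per_station), total_length=551.0)

F, G = rh.overall_functions(per_station, layout)
print(f"whole-river F = {F:.3f}, G = {G:.3f}")

result = rh.overall_assessment(per_station, layout, w_natural=0.67, w_social=0.33)
print(
    f"C_s = {result.coordination:.3f}, T_s = {result.composite:.3f}, "
    f"D_s = {result.development:.3f}, E_s = {result.relative:.3f}"
)
print(rh.grade_state(result.composite), "/", rh.grade_coordination(result.development))
# With equal segments F and G are the plain means of the station values;
# unequal lengths shift the whole-river result toward the longest segments.
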