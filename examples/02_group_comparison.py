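"""Treated-vs-control cohort comparison.

Generates the default study design (5 strongly coordinated treated animals,
7 weakly coordinated controls), analyzes every recording, and runs the
between-group battery: Student's t on per-animal means and CVs, and
Mann-Whitney on coordination r-values (bounded on [0, 1]).
"""

import emgait as eg

recs = eg.generate_cohort(eg.treated_config(seed=7), eg.control_config(seed=7))
metrics, coord = eg.analyze_cohort(recs)

sol_amp = metrics[(metrics.muscle == "Sol-L") & (metrics.parameter == "peak_amplitude")]
a_t = sol_amp[sol_amp.group == "TTx2EB"]["mean"].to_numpy()
a_c = sol_amp[sol_amp.group == "TTnoEB"]["mean"].to_numpy()
res = eg.compare_groups(eg.GroupDataset("sol_amplitude", a_t, a_c), "student_t")
print(f"Sol peak amplitude: treated {a_t.mean():.3f} vs control {a_c.mean():.3f} "
      f"(+{100 * (a_t.mean() / a_c.mean() - 1):.0f}%), t-test p = {res.p_value:.2g}")

cyc = metrics[(metrics.muscle == "Sol-L") & (metrics.parameter == "cycle_duration")]
m_t = cyc[cyc.group == "TTx2EB"]
m_c = cyc[cyc.group == "TTnoEB"]
res = eg.compare_groups(
    eg.GroupDataset("cycle", m_t["mean"].to_numpy(), m_c["mean"].to_numpy()), "student_t"
)
print(f"cycle duration:     treated {m_t['mean'].mean():.3f} s vs control "
      f"{m_c['mean'].mean():.3f} s, t-test p = {res.p_value:.3f} (no difference expected)")
res = eg.compare_cv(eg.GroupDataset("cycle_cv", m_t.cv.to_numpy(), m_c.cv.to_numpy()))
print(f"cycle-duration CV:  treated {m_t.cv.mean():.3f} vs control {m_c.cv.mean():.3f}, "
      f"t-test p = {res.p_value:.2g} (treated gait is steadier)")

inter = coord[coord.pairing == "interlimb"]
r_t = inter[inter.group == "TTx2EB"].r.to_numpy()
r_c = inter[inter.group == "TTnoEB"].r.to_numpy()
res = eg.compare_groups(eg.GroupDataset("interlimb_r", r_t, r_c), "mann_whitney")
print(f"interlimb r:        treated {r_t.mean():.3f} vs control {r_c.mean():.3f}, "
      f"Mann-Whitney p = {res.p_value:.4f}")
print(f"coordinated animals: treated {inter[inter.group == 'TTx2EB'].coordinated.sum()}/5, "
      f"control {inter[inter.group == 'TTnoEB'].coordinated.sum()}/7")

print("\nThe treated cohort shows stronger, less variable muscle activity and")
print("significant left/right alternation; controls step irregularly with")
print("phase coupling below the critical Rayleigh value.")
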