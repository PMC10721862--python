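"""DMN connectivity and sample entropy for one psilocybin session."""

from psiloconn import connectivity, dmn, preprocess, synthetic

subject = synthetic.generate_cohort(0, 1, seed=0).subjects[0]
session = synthetic.simulate_session(subject, "psilocybin",
                                     synthetic.EffectSpec(), seed=5)
clean, epochs, _ = preprocess.preprocess_session(
    session.roi_ts, session.motion, tr=session.tr)

c1 = connectivity.fc_matrix(clean[:, epochs.slice1()], session.region_labels, "TP1")
c2 = connectivity.fc_matrix(clean[:, epochs.slice2()], session.region_labels, "TP2")
m1, s1 = dmn.dmn_connectivity(c1)
m2, s2 = dmn.dmn_connectivity(c2)
print(f"mean DMN connectivity (Fisher z): pre {m1:.3f} -> post {m2:.3f} "
      f"(change {m2 - m1:+.3f}; the injected psilocybin effect lowers it)")
drops = (s2 - s1).sort_values()
print("largest within-DMN strength decreases:")
print(drops.head(3).round(3).to_string())

params = dmn.SampEnParams(m=3, r=0.2)
e1 = dmn.regional_entropy_roi(clean[:, epochs.slice1()], session.region_labels,
                              params)
e2 = dmn.regional_entropy_roi(clean[:, epochs.slice2()], session.region_labels,
                              params)
print(f"\nDMN sample entropy (m=3, r=0.2): pre {dmn.dmn_mean(e1):.3f} -> "
      f"post {dmn.dmn_mean(e2):.3f}")
print("(SampEn = -ln(A/B); higher values = less regular BOLD signal)")
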