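# Low-frequency electrical conductivities for head tissues at the 2.5 kHz
# pulse-equivalent TMS frequency, in S/m.
# Values follow the standard low-frequency head-modeling set consistent with
# the Gabriel-family parametric dielectric database as adopted by mainstream
# TMS dosimetry pipelines (scalp 0.465, compact skull 0.010, CSF 1.654,
# gray matter 0.275, white matter 0.126); deep gray-matter structures take
# the gray-matter value. Table version: deeptms-1.
# hemisphere_splittable marks tissues reported per hemisphere (bilateral or
# midline-spanning structures).
tissue,sigma_S_per_m,hemisphere_splittable
scalp,0.465,0
skull,0.010,0
csf,1.654,0
gray_matter,0.275,1
white_matter,0.126,1
cerebellum,0.275,1
hippocampus,0.275,1
nucleus_accumbens,0.275,1
thalamus,0.275,0
hypothalamus,0.275,0
amygdala,0.275,1
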