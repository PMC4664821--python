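subject,age,affected_side,lesion_location,years_since_stroke,fugl_meyer,mep_pre_uv,mep_post_uv
S1,53,R,L brainstem,7,59,832.4,403.9
S2,60,R,L occipital,4,52,1209.3,661.8
S3,58,R,"L primary sensorimotor area, internal capsule, and caudate nucleus",7,55,667.8,260.1
S4,68,L,N/A,4.5,54,679.5,138.6
S5,62,L,R occipital,6.5,45,1206.8,700.6
S6,59,R,L pontine,3,55,885.1,274.7
S7,54,L,N/A,2.5,60,484.8,395.4
S8,48,L,N/A,3.6,50,293.9,447.2
S9,69,L,N/A,0.6,55,909.3,885.1
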