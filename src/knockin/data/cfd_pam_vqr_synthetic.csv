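# SYNTHETIC PAM-factor table for SpCas9-VQR (NGA PAM). No published CFD PAM
# table for the VQR variant is vendored here; these factors encode the
# variant's known PAM preference (NGA canonical, residual NGG activity,
# negligible activity otherwise) and are a constructed stand-in.
# Key is the two variable bases of the N[XY] PAM.
pam,factor
AA,0.0
AC,0.0
AG,0.02
AT,0.0
CA,0.0
CC,0.0
CG,0.01
CT,0.0
GA,1.0
GC,0.01
GG,0.25
GT,0.01
TA,0.0
TC,0.0
TG,0.01
TT,0.0
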