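# Calibrated default parameter set, titration-of-nuclear-sites model
# (haploid wild type).  Units: AU (amount), AV (volume), arbitrary time.
variant: titration
# --- genome configuration ---
GDt: 200
GIt: 1
GCN: 1
GWt: 1
GCt: 1
NSt: 4
# --- gene expression core ---
kGiTmAs: 5000.0
kGiTmDs: 0.1
kGdTmAs: 100.0
kGdTmDs: 1.0
kTmSy: 1.4
kVoSy: 1.4
kPiSy: 1.0
kPdSy: 1.0
kPiDe: 0.05
kPdDe: 0.05
# --- cyclins ---
kCln3Sy: 30.0
kClnSy: 40.0
kClbSy: 0.2
kClbClbSy: 6.0
jClbSy: 0.02
kCln3De: 1.0
kClnDe: 1.0
kClbDe: 0.1
kClbCdhDe: 6.0
# --- Whi5 / SBF on nuclear sites ---
kWhiSbfAs: 10.0
kWhiSbfDs: 0.0
kWhiDp: 1.0
kSbfDp: 0.05
kWhiSy: 0.1
kWhiCln3Ph: 0.3
kWhiClnPh: 100.0
kWhiClbPh: 0.0
kSbfClbPh: 20.0
kCln3WhiAs: 2000.0
kCln3WhiDs: 0.05
kWhipCln3Ph: 50.0
kWhipClnPh: 50.0
# --- APC/C ---
kCdhAc: 0.05
kCdhCdcAc: 5.0
kCdhClnIn: 3.0
kCdhClbIn: 5.0
kCdcClbAc: 0.02
kCdcIn: 0.005
jCdh: 0.05
jCdc: 0.1
# --- event thresholds ---
StartThr: 0.05
MitosisThr: 0.04
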