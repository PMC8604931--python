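name,monoisotopic_mass,class
"LysoPC(16:1/0:0)",493.316827,glycerophospholipids
"LysoPC(18:2/0:0)",519.332477,glycerophospholipids
betaine,117.078979,organic acids and derivatives
indole,117.057849,organoheterocyclic compounds
creatinine,113.058912,organoheterocyclic compounds
taurine,125.014664,organosulfur compounds
hypoxanthine,136.038511,nucleotide-related
glycine,75.032028,organic acids and derivatives
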