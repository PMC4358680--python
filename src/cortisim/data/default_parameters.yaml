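gCa: 1.8
gNS: 0.1
gK: 8.2
gKir: 1.0
gBKnear: 2.0
gBKfar: 1.0
VCa: 60.0
VNS: -10.0
VK: -75.0
vr: -60.0
vm: -20.0
vn: -5.0
sm: 10.0
sn: 10.0
sr: -1.0
taubkn: 20.0
taubkf: 4.0
taun: 40.0
kCaBKnear: 18.0
kCaBKfar: 6.0
kbk: 3.0
VBK0: 0.1
kshift: 18.0
A: 0.15
kc: 0.12
f: 0.01
alpha: 0.0015
sigmaN: 5.0
Cm: 6.0
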