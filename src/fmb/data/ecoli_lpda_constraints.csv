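reaction_id,condition,mean,sigma,class
GLCpts,control,-3.04,0.01824,FMT
GLCpts,perturbed,-2.48,0.1488,FMT
BiomassEcoli,control,0.20,0.0100,FMT
BiomassEcoli,perturbed,0.22,0.0110,FMT
PGI,control,2.39,0.3107,C13
PGI,perturbed,1.79,0.2327,C13
PYK,control,1.09,0.0109,C13
PYK,perturbed,0.26,0.0026,C13
G6PDH2r,control,0.61,0.0732,C13
G6PDH2r,perturbed,0.64,0.0768,C13
GND,control,0.61,0.0732,C13
GND,perturbed,0.32,0.0384,C13
PPC,control,0.67,0.0469,C13
PPC,perturbed,1.61,0.1127,C13
PPCK,control,0.07,0.0070,C13
PPCK,perturbed,0.93,0.0930,C13
PDH,control,3.56,0.2136,C13
PDH,perturbed,0.00,0.0000,C13
AKGDH,perturbed,0.00,0.0000,C13
GLYCL,perturbed,0.00,0.0000,C13
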