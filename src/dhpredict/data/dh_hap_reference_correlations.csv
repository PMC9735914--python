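trait,tissue,trait_class,env,h2_D,h2_H,rP,rG
EI::DryWeight,EI,agronomic,BJ2014,0.37,0.32,0.35,0.72
EI::DryWeight,EI,agronomic,SJZ2014,0.39,0.28,0.42,0.72
EI::FreshWeight,EI,agronomic,BJ2014,0.45,0.38,0.4,0.77
EI::FreshWeight,EI,agronomic,SJZ2014,0.53,0.39,0.48,0.82
EI::InternodeDiameter,EI,agronomic,BJ2014,0.26,0.26,0.31,0.62
EI::InternodeDiameter,EI,agronomic,SJZ2014,0.46,0.37,0.42,0.8
EI::InternodeLength,EI,agronomic,BJ2014,0.37,0.37,0.38,0.77
EI::InternodeLength,EI,agronomic,SJZ2014,0.48,0.47,0.48,0.79
EI::mRPR,EI,agronomic,BJ2014,0.21,0.2,0.09,0.21
EI::mRPR,EI,agronomic,SJZ2014,0.56,0.53,0.51,0.88
FI::DryWeight,FI,agronomic,BJ2014,0.29,0.22,0.24,0.57
FI::DryWeight,FI,agronomic,SJZ2014,0.47,0.42,0.44,0.78
FI::FreshWeight,FI,agronomic,BJ2014,0.36,0.25,0.34,0.63
FI::FreshWeight,FI,agronomic,SJZ2014,0.54,0.45,0.51,0.83
FI::InternodeDiameter,FI,agronomic,BJ2014,0.25,0.32,0.27,0.62
FI::InternodeDiameter,FI,agronomic,SJZ2014,0.45,0.45,0.41,0.8
FI::InternodeLength,FI,agronomic,BJ2014,0.54,0.32,0.38,0.73
FI::InternodeLength,FI,agronomic,SJZ2014,0.41,0.27,0.32,0.57
FI::mRPR,FI,agronomic,BJ2014,0.39,0.44,0.4,0.79
FI::mRPR,FI,agronomic,SJZ2014,0.61,0.44,0.5,0.86
WP::DryWeight,WP,agronomic,BJ2014,0.36,0.44,0.44,0.78
WP::DryWeight,WP,agronomic,SJZ2014,0.54,0.51,0.59,0.88
WP::EarHeight,WP,agronomic,BJ2014,0.64,0.47,0.55,0.83
WP::EarHeight,WP,agronomic,SJZ2014,0.52,0.59,0.59,0.83
WP::FreshWeight,WP,agronomic,BJ2014,0.44,0.41,0.46,0.78
WP::FreshWeight,WP,agronomic,SJZ2014,0.62,0.51,0.61,0.89
WP::LeafAngle,WP,agronomic,BJ2014,0.6,0.61,0.48,0.85
WP::LeafAngle,WP,agronomic,SJZ2014,0.7,0.51,0.42,0.76
WP::LeafLength,WP,agronomic,BJ2014,0.66,0.56,0.63,0.89
WP::LeafLength,WP,agronomic,SJZ2014,0.58,0.64,0.64,0.91
WP::LeafWidth,WP,agronomic,BJ2014,0.36,0.36,0.46,0.79
WP::LeafWidth,WP,agronomic,SJZ2014,0.3,0.41,0.34,0.66
WP::PlantHeight,WP,agronomic,BJ2014,0.53,0.43,0.52,0.82
WP::PlantHeight,WP,agronomic,SJZ2014,0.49,0.57,0.54,0.8
EI::ADF,EI,stalk,BJ2014,0.32,0.32,0.41,0.71
EI::ADF,EI,stalk,SJZ2014,0.37,0.39,0.37,0.64
EI::ASH,EI,stalk,BJ2014,0.22,0.25,0.22,0.53
EI::ASH,EI,stalk,SJZ2014,0.33,0.26,0.33,0.59
EI::Cellulose,EI,stalk,BJ2014,0.14,0.2,0.14,0.3
EI::Cellulose,EI,stalk,SJZ2014,0.26,0.27,0.3,0.52
EI::CP,EI,stalk,BJ2014,0.31,0.29,0.36,0.72
EI::CP,EI,stalk,SJZ2014,0.32,0.24,0.28,0.52
EI::FAT,EI,stalk,BJ2014,0.21,0.2,0.19,0.43
EI::FAT,EI,stalk,SJZ2014,0.24,0.16,0.15,0.32
EI::IVDMD,EI,stalk,BJ2014,0.3,0.27,0.42,0.71
EI::IVDMD,EI,stalk,SJZ2014,0.34,0.31,0.31,0.53
EI::Lignin,EI,stalk,BJ2014,0.26,0.24,0.34,0.59
EI::Lignin,EI,stalk,SJZ2014,0.35,0.26,0.23,0.55
EI::NDF,EI,stalk,BJ2014,0.41,0.36,0.53,0.79
EI::NDF,EI,stalk,SJZ2014,0.37,0.29,0.34,0.62
EI::WSC,EI,stalk,BJ2014,0.29,0.28,0.38,0.67
EI::WSC,EI,stalk,SJZ2014,0.27,0.21,0.27,0.45
FI::ADF,FI,stalk,BJ2014,0.39,0.4,0.49,0.81
FI::ADF,FI,stalk,SJZ2014,0.36,0.31,0.29,0.59
FI::ASH,FI,stalk,BJ2014,0.17,0.24,0.21,0.46
FI::ASH,FI,stalk,SJZ2014,0.23,0.26,0.19,0.37
FI::Cellulose,FI,stalk,BJ2014,0.22,0.3,0.3,0.64
FI::Cellulose,FI,stalk,SJZ2014,0.29,0.3,0.3,0.53
FI::CP,FI,stalk,BJ2014,0.28,0.28,0.27,0.56
FI::CP,FI,stalk,SJZ2014,0.32,0.28,0.23,0.49
FI::FAT,FI,stalk,BJ2014,0.17,0.22,0.06,0.26
FI::FAT,FI,stalk,SJZ2014,0.19,0.15,0.06,0.14
FI::IVDMD,FI,stalk,BJ2014,0.39,0.34,0.5,0.8
FI::IVDMD,FI,stalk,SJZ2014,0.4,0.34,0.29,0.6
FI::Lignin,FI,stalk,BJ2014,0.2,0.2,0.25,0.47
FI::Lignin,FI,stalk,SJZ2014,0.38,0.29,0.22,0.47
FI::NDF,FI,stalk,BJ2014,0.4,0.35,0.51,0.79
FI::NDF,FI,stalk,SJZ2014,0.39,0.29,0.31,0.63
FI::WSC,FI,stalk,BJ2014,0.24,0.27,0.34,0.65
FI::WSC,FI,stalk,SJZ2014,0.32,0.28,0.32,0.62
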