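region_label,subnetwork_label
R000,BGN
R001,BGN
R002,BGN
R003,BGN
R004,CEREN
R005,CEREN
R006,CEREN
R007,CEREN
R008,DAN
R009,DAN
R010,DAN
R011,DAN
R012,DMN
R013,DMN
R014,DMN
R015,DMN
R016,FPN
R017,FPN
R018,FPN
R019,FPN
R020,LN
R021,LN
R022,LN
R023,LN
R024,SMN
R025,SMN
R026,SMN
R027,SMN
R028,VAN
R029,VAN
R030,VAN
R031,VAN
R032,VN
R033,VN
R034,VN
R035,VN
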