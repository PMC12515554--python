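encounter_id,score,tfc_high
E001,0,1
E002,1,1
E003,1,1
E004,1,1
E005,2,1
E006,2,1
E007,3,1
E008,3,1
E009,3,1
E010,3,1
E011,3,1
E012,3,1
E013,3,1
E014,3,1
E015,3,1
E016,3,1
E017,4,1
E018,4,1
E019,4,1
E020,4,1
E021,4,1
E022,4,1
E023,4,1
E024,4,1
E025,4,1
E026,4,1
E027,4,1
E028,4,1
E029,4,1
E030,4,1
E031,5,1
E032,5,1
E033,5,1
E034,5,1
E035,5,1
E036,5,1
E037,5,1
E038,5,1
E039,5,1
E040,5,1
E041,5,1
E042,5,1
E043,5,1
E044,5,1
E045,5,1
E046,5,1
E047,5,1
E048,5,1
E049,5,1
E050,5,1
E051,6,1
E052,6,1
E053,6,1
E054,6,1
E055,6,1
E056,6,1
E057,6,1
E058,6,1
E059,6,1
E060,6,1
E061,7,1
E062,7,1
E063,7,1
E064,7,1
E065,7,1
E066,7,1
E067,7,1
E068,7,1
E069,7,1
E070,8,1
E071,8,1
E072,8,1
E073,8,1
E074,8,1
E075,8,1
E076,8,1
E077,8,1
E078,8,1
E079,0,0
E080,0,0
E081,0,0
E082,0,0
E083,0,0
E084,0,0
E085,0,0
E086,0,0
E087,0,0
E088,0,0
E089,0,0
E090,0,0
E091,1,0
E092,1,0
E093,1,0
E094,1,0
E095,1,0
E096,1,0
E097,1,0
E098,1,0
E099,2,0
E100,2,0
E101,2,0
E102,2,0
E103,2,0
E104,2,0
E105,2,0
E106,3,0
E107,3,0
E108,3,0
E109,3,0
E110,3,0
E111,4,0
E112,4,0
E113,4,0
E114,4,0
E115,5,0
E116,7,0
E117,8,0
E118,8,0
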