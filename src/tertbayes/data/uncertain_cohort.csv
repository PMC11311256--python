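lesion_id,preliminary_category,mutant_droplets_c228t,total_droplets_c228t,mutant_droplets_c250t,total_droplets_c250t,tertp_status
L001,likely_benign,0,710,0,710,wildtype
L002,likely_benign,0,720,0,720,wildtype
L003,likely_benign,0,730,0,730,wildtype
L004,likely_benign,0,740,0,740,wildtype
L005,likely_benign,0,750,0,750,wildtype
L006,likely_benign,0,760,0,760,wildtype
L007,likely_benign,0,770,0,770,wildtype
L008,likely_benign,0,780,0,780,wildtype
L009,likely_benign,0,790,0,790,wildtype
L010,likely_benign,0,800,0,800,wildtype
L011,likely_benign,0,810,0,810,wildtype
L012,likely_benign,0,820,0,820,wildtype
L013,likely_benign,0,830,0,830,wildtype
L014,likely_benign,0,840,0,840,wildtype
L015,likely_benign,0,850,0,850,wildtype
L016,likely_benign,0,860,0,860,wildtype
L017,likely_benign,0,870,0,870,wildtype
L018,likely_benign,0,880,0,880,wildtype
L019,likely_benign,0,890,0,890,wildtype
L020,likely_benign,0,900,0,900,wildtype
L021,likely_benign,0,910,0,910,wildtype
L022,likely_benign,0,920,0,920,wildtype
L023,likely_benign,0,930,0,930,wildtype
L024,likely_benign,0,940,0,940,wildtype
L025,likely_benign,0,700,0,700,wildtype
L026,likely_benign,0,710,0,710,wildtype
L027,likely_benign,0,720,0,720,wildtype
L028,likely_benign,0,730,0,730,wildtype
L029,likely_benign,0,740,0,740,wildtype
L030,likely_benign,0,750,0,750,wildtype
L031,likely_benign,0,760,0,760,wildtype
L032,likely_benign,0,770,0,770,wildtype
L033,likely_benign,0,780,0,780,wildtype
L034,likely_benign,0,790,0,790,wildtype
L035,likely_benign,0,800,0,800,wildtype
L036,likely_benign,0,810,0,810,wildtype
L037,likely_benign,0,820,0,820,wildtype
L038,likely_benign,0,830,0,830,wildtype
L039,likely_benign,0,840,0,840,wildtype
L040,likely_benign,0,850,0,850,wildtype
L041,likely_benign,0,860,0,860,wildtype
L042,likely_benign,0,870,0,870,wildtype
L043,likely_benign,0,880,0,880,wildtype
L044,likely_benign,0,890,0,890,wildtype
L045,likely_benign,0,75,0,75,inconclusive
L046,likely_benign,0,80,0,80,inconclusive
L047,likely_benign,0,85,0,85,inconclusive
L048,likely_benign,0,90,0,90,inconclusive
L049,likely_benign,0,95,0,95,inconclusive
L050,ambiguous,0,700,0,700,wildtype
L051,ambiguous,0,710,0,710,wildtype
L052,ambiguous,0,720,0,720,wildtype
L053,ambiguous,0,730,0,730,wildtype
L054,ambiguous,0,740,0,740,wildtype
L055,ambiguous,0,750,0,750,wildtype
L056,ambiguous,0,760,0,760,wildtype
L057,ambiguous,0,770,0,770,wildtype
L058,ambiguous,0,780,0,780,wildtype
L059,ambiguous,0,790,0,790,wildtype
L060,ambiguous,0,800,0,800,wildtype
L061,ambiguous,0,810,0,810,wildtype
L062,ambiguous,0,820,0,820,wildtype
L063,ambiguous,0,830,0,830,wildtype
L064,ambiguous,0,840,0,840,wildtype
L065,ambiguous,0,850,0,850,wildtype
L066,ambiguous,0,860,0,860,wildtype
L067,ambiguous,0,870,0,870,wildtype
L068,ambiguous,0,880,0,880,wildtype
L069,ambiguous,0,890,0,890,wildtype
L070,ambiguous,0,900,0,900,wildtype
L071,ambiguous,0,910,0,910,wildtype
L072,ambiguous,0,920,0,920,wildtype
L073,ambiguous,0,930,0,930,wildtype
L074,ambiguous,0,940,0,940,wildtype
L075,ambiguous,0,700,0,700,wildtype
L076,ambiguous,0,710,0,710,wildtype
L077,ambiguous,0,720,0,720,wildtype
L078,ambiguous,0,730,0,730,wildtype
L079,ambiguous,0,740,0,740,wildtype
L080,ambiguous,0,750,0,750,wildtype
L081,ambiguous,0,760,0,760,wildtype
L082,ambiguous,0,770,0,770,wildtype
L083,ambiguous,0,780,0,780,wildtype
L084,ambiguous,0,790,0,790,wildtype
L085,ambiguous,0,800,0,800,wildtype
L086,ambiguous,0,810,0,810,wildtype
L087,ambiguous,0,820,0,820,wildtype
L088,ambiguous,0,830,0,830,wildtype
L089,ambiguous,0,840,0,840,wildtype
L090,ambiguous,0,850,0,850,wildtype
L091,ambiguous,0,860,0,860,wildtype
L092,ambiguous,0,870,0,870,wildtype
L093,ambiguous,0,880,0,880,wildtype
L094,ambiguous,0,890,0,890,wildtype
L095,ambiguous,0,900,0,900,wildtype
L096,ambiguous,0,910,0,910,wildtype
L097,ambiguous,0,920,0,920,wildtype
L098,ambiguous,0,930,0,930,wildtype
L099,ambiguous,0,940,0,940,wildtype
L100,ambiguous,0,700,0,700,wildtype
L101,ambiguous,0,710,0,710,wildtype
L102,ambiguous,0,720,0,720,wildtype
L103,ambiguous,0,730,0,730,wildtype
L104,ambiguous,0,740,0,740,wildtype
L105,ambiguous,35,850,0,750,mutated
L106,ambiguous,36,860,0,760,mutated
L107,ambiguous,37,870,0,770,mutated
L108,ambiguous,38,880,0,780,mutated
L109,ambiguous,39,890,0,790,mutated
L110,ambiguous,40,900,0,800,mutated
L111,ambiguous,0,810,41,910,mutated
L112,ambiguous,0,820,42,920,mutated
L113,ambiguous,0,830,43,930,mutated
L114,ambiguous,0,840,44,940,mutated
L115,ambiguous,0,850,45,950,mutated
L116,ambiguous,0,860,46,960,mutated
L117,ambiguous,0,870,47,970,mutated
L118,ambiguous,0,880,48,980,mutated
L119,ambiguous,0,145,0,145,inconclusive
L120,ambiguous,0,50,0,50,inconclusive
L121,ambiguous,0,55,0,55,inconclusive
L122,ambiguous,0,60,0,60,inconclusive
L123,ambiguous,0,65,0,65,inconclusive
L124,ambiguous,0,70,0,70,inconclusive
L125,ambiguous,0,75,0,75,inconclusive
L126,ambiguous,0,80,0,80,inconclusive
L127,ambiguous,0,85,0,85,inconclusive
L128,ambiguous,0,90,0,90,inconclusive
L129,ambiguous,0,95,0,95,inconclusive
L130,ambiguous,0,100,0,100,inconclusive
L131,ambiguous,0,105,0,105,inconclusive
L132,ambiguous,0,110,0,110,inconclusive
L133,ambiguous,0,115,0,115,inconclusive
L134,ambiguous,0,120,0,120,inconclusive
L135,ambiguous,0,125,0,125,inconclusive
L136,ambiguous,0,130,0,130,inconclusive
L137,likely_malignant,0,820,0,820,wildtype
L138,likely_malignant,0,830,0,830,wildtype
L139,likely_malignant,0,840,0,840,wildtype
L140,likely_malignant,0,850,0,850,wildtype
L141,likely_malignant,0,860,0,860,wildtype
L142,likely_malignant,0,870,0,870,wildtype
L143,likely_malignant,0,880,0,880,wildtype
L144,likely_malignant,0,890,0,890,wildtype
L145,likely_malignant,0,900,0,900,wildtype
L146,likely_malignant,0,910,0,910,wildtype
L147,likely_malignant,0,920,0,920,wildtype
L148,likely_malignant,0,930,0,930,wildtype
L149,likely_malignant,0,940,0,940,wildtype
L150,likely_malignant,40,800,0,700,mutated
L151,likely_malignant,41,810,0,710,mutated
L152,likely_malignant,42,820,0,720,mutated
L153,likely_malignant,43,830,0,730,mutated
L154,likely_malignant,44,840,0,740,mutated
L155,likely_malignant,45,850,0,750,mutated
L156,likely_malignant,46,860,0,760,mutated
L157,likely_malignant,0,770,47,870,mutated
L158,likely_malignant,0,780,48,880,mutated
L159,likely_malignant,0,790,49,890,mutated
L160,likely_malignant,0,800,10,900,mutated
L161,likely_malignant,0,810,11,910,mutated
L162,likely_malignant,0,820,12,920,mutated
L163,likely_malignant,0,830,13,930,mutated
L164,likely_malignant,0,840,14,940,mutated
L165,likely_malignant,0,850,15,950,mutated
L166,likely_malignant,0,860,16,960,mutated
L167,likely_malignant,0,870,17,970,mutated
L168,likely_malignant,0,880,18,980,mutated
L169,likely_malignant,0,890,19,990,mutated
L170,likely_malignant,0,900,20,1000,mutated
L171,likely_malignant,0,910,21,1010,mutated
L172,likely_malignant,0,920,22,1020,mutated
L173,likely_malignant,0,930,23,1030,mutated
L174,likely_malignant,0,940,24,1040,mutated
L175,likely_malignant,0,125,0,125,inconclusive
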