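{
"vocab": [
"[PAD]",
"[SOS]",
"[EOS]",
"[UNK]",
",",
",</w>",
"-",
"-</w>",
".",
".</w>",
"0",
"00</w>",
"0</w>",
"1",
"1</w>",
"2",
"2</w>",
"3",
"3.0</w>",
"4",
"4</w>",
"5",
"5</w>",
"6",
"6</w>",
"7",
"8",
"8</w>",
"9",
"9</w>",
"</w>",
"a",
"a</w>",
"abdomen</w>",
"acquired</w>",
"ag",
"agent</w>",
"al</w>",
"an",
"an</w>",
"attenuated</w>",
"axial</w>",
"b",
"beam</w>",
"brain</w>",
"breast</w>",
"c",
"ce</w>",
"computed</w>",
"cone</w>",
"consist</w>",
"consists</w>",
"contrast</w>",
"d",
"d</w>",
"dce</w>",
"e",
"e</w>",
"ec",
"en",
"enhanced</w>",
"es</w>",
"f",
"fl",
"flair</w>",
"fluid</w>",
"fo",
"for</w>",
"g",
"gadolinium</w>",
"h",
"i",
"ig",
"ili",
"image</w>",
"imaging</w>",
"in</w>",
"ing",
"ing</w>",
"inversion</w>",
"ir",
"ir</w>",
"is",
"is</w>",
"j",
"k",
"l",
"m",
"magnetic</w>",
"ms</w>",
"n",
"o",
"of</w>",
"on",
"on</w>",
"p",
"p</w>",
"pe",
"pelvis</w>",
"ph",
"plane</w>",
"pr",
"preprocessing</w>",
"pti",
"q",
"r",
"r</w>",
"ra",
"re",
"recovery</w>",
"resonance</w>",
"s",
"s</w>",
"sat",
"scan",
"scan</w>",
"scanner</w>",
"sequen",
"si",
"sing</w>",
"sk",
"sp</w>",
"st</w>",
"star</w>",
"subject</w>",
"susceptibility</w>",
"t",
"t1</w>",
"t2</w>",
"t</w>",
"tesla</w>",
"th",
"th</w>",
"the</w>",
"ti",
"time</w>",
"tion</w>",
"tomography</w>",
"ts</w>",
"u",
"undergoes</w>",
"v",
"visualized</w>",
"w",
"weighted</w>",
"with</w>",
"x",
"y",
"z"
],
"merges": [
[
"e",
"</w>"
],
[
"t",
"h"
],
[
"th",
"e</w>"
],
[
"d",
"</w>"
],
[
"e",
"d</w>"
],
[
"i",
"s"
],
[
".",
"</w>"
],
[
"a",
"l"
],
[
"i",
"n"
],
[
"a",
"g"
],
[
"m",
"ag"
],
[
"a",
"n"
],
[
"t",
"</w>"
],
[
"i",
"mag"
],
[
"o",
"m"
],
[
"t",
"ed</w>"
],
[
"is",
"</w>"
],
[
"r",
"</w>"
],
[
"in",
"</w>"
],
[
"e",
"c"
],
[
"s",
"u"
],
[
"o",
"f"
],
[
"of",
"</w>"
],
[
"a",
"</w>"
],
[
"su",
"b"
],
[
"sub",
"j"
],
[
"subj",
"ec"
],
[
"subjec",
"t</w>"
],
[
"imag",
"e</w>"
],
[
"al",
"</w>"
],
[
"z",
"ed</w>"
],
[
"v",
"is"
],
[
"vis",
"u"
],
[
"visu",
"al"
],
[
"visual",
"i"
],
[
"visuali",
"zed</w>"
],
[
"p",
"l"
],
[
"pl",
"an"
],
[
"plan",
"e</w>"
],
[
"x",
"i"
],
[
"xi",
"al</w>"
],
[
"o",
"n"
],
[
"f",
"o"
],
[
"a",
"xial</w>"
],
[
"fo",
"r</w>"
],
[
"r",
"a"
],
[
"y",
"</w>"
],
[
"-",
"</w>"
],
[
"r",
"e"
],
[
"p",
"h"
],
[
"u",
"ted</w>"
],
[
"t",
"om"
],
[
"tom",
"o"
],
[
"tomo",
"g"
],
[
"tomog",
"ra"
],
[
"tomogra",
"ph"
],
[
"tomograph",
"y</w>"
],
[
"p",
"uted</w>"
],
[
"om",
"puted</w>"
],
[
"c",
"omputed</w>"
],
[
"i",
"g"
],
[
"w",
"e"
],
[
"we",
"ig"
],
[
"weig",
"h"
],
[
"weigh",
"ted</w>"
],
[
"t",
"i"
],
[
"c",
"e</w>"
],
[
"in",
"g"
],
[
"ing",
"</w>"
],
[
"e",
"n"
],
[
"imag",
"ing</w>"
],
[
"c",
"on"
],
[
"n",
"e"
],
[
"m",
"</w>"
],
[
"ti",
"c"
],
[
"tic",
"</w>"
],
[
"s",
"t</w>"
],
[
"s",
"on"
],
[
"son",
"an"
],
[
"sonan",
"ce</w>"
],
[
"re",
"sonance</w>"
],
[
"ne",
"tic</w>"
],
[
"mag",
"netic</w>"
],
[
"2",
"</w>"
],
[
"t",
"2</w>"
],
[
"e",
"r"
],
[
"e",
"a"
],
[
"ea",
"m</w>"
],
[
"con",
"e</w>"
],
[
"b",
"eam</w>"
],
[
"re",
"a"
],
[
"rea",
"st</w>"
],
[
"b",
"reast</w>"
],
[
"s",
"c"
],
[
"v",
"er"
],
[
"p",
"e"
],
[
"f",
"l"
],
[
"v",
"is</w>"
],
[
"ra",
"in</w>"
],
[
"pe",
"l"
],
[
"pel",
"vis</w>"
],
[
"om",
"en"
],
[
"omen",
"</w>"
],
[
"d",
"omen</w>"
],
[
"b",
"rain</w>"
],
[
"b",
"domen</w>"
],
[
"a",
"bdomen</w>"
],
[
"s",
"</w>"
],
[
"on",
"</w>"
],
[
"d",
"ce</w>"
],
[
"u",
"i"
],
[
"sc",
"an"
],
[
"s",
"i"
],
[
"a",
"t"
],
[
"1",
"</w>"
],
[
"ver",
"si"
],
[
"versi",
"on</w>"
],
[
"p",
"ti"
],
[
"l",
"i"
],
[
"in",
"version</w>"
],
[
"i",
"r</w>"
],
[
"i",
"li"
],
[
"ver",
"y</w>"
],
[
"ui",
"d</w>"
],
[
"u",
"a"
],
[
"ua",
"ted</w>"
],
[
"t",
"y</w>"
],
[
"t",
"en"
],
[
"ten",
"uated</w>"
],
[
"t",
"a"
],
[
"ta",
"r</w>"
],
[
"t",
"1</w>"
],
[
"su",
"sc"
],
[
"susc",
"e"
],
[
"susce",
"pti"
],
[
"suscepti",
"b"
],
[
"susceptib",
"ili"
],
[
"susceptibili",
"ty</w>"
],
[
"s",
"tar</w>"
],
[
"r",
"ec"
],
[
"rec",
"o"
],
[
"reco",
"very</w>"
],
[
"fl",
"uid</w>"
],
[
"fl",
"a"
],
[
"fla",
"ir</w>"
],
[
"at",
"tenuated</w>"
],
[
"scan",
"</w>"
],
[
",",
"</w>"
],
[
"th",
"</w>"
],
[
"e",
"s</w>"
],
[
"0",
"</w>"
],
[
"w",
"i"
],
[
"wi",
"th</w>"
],
[
"u",
"n"
],
[
"un",
"d"
],
[
"und",
"er"
],
[
"under",
"g"
],
[
"underg",
"o"
],
[
"undergo",
"es</w>"
],
[
"u",
"m</w>"
],
[
"t",
"ra"
],
[
"tra",
"st</w>"
],
[
"o",
"l"
],
[
"ol",
"in"
],
[
"olin",
"i"
],
[
"olini",
"um</w>"
],
[
"h",
"an"
],
[
"han",
"c"
],
[
"hanc",
"ed</w>"
],
[
"g",
"a"
],
[
"ga",
"d"
],
[
"gad",
"olinium</w>"
],
[
"en",
"t</w>"
],
[
"en",
"hanced</w>"
],
[
"con",
"trast</w>"
],
[
"ag",
"ent</w>"
],
[
"p",
"</w>"
],
[
"s",
"is"
],
[
"e",
"s"
],
[
"con",
"sis"
],
[
"ui",
"r"
],
[
"uir",
"ed</w>"
],
[
"q",
"uired</w>"
],
[
"c",
"quired</w>"
],
[
"a",
"cquired</w>"
],
[
"ti",
"m"
],
[
"tim",
"e</w>"
],
[
"t",
"s</w>"
],
[
"t",
"es"
],
[
"tes",
"l"
],
[
"tesl",
"a</w>"
],
[
"scan",
"ne"
],
[
"scanne",
"r</w>"
],
[
"s",
"ing</w>"
],
[
"p",
"r"
],
[
"m",
"s</w>"
],
[
"consis",
"t</w>"
],
[
"u",
"en"
],
[
"ti",
"on</w>"
],
[
"s",
"p</w>"
],
[
"s",
"k"
],
[
"s",
"e"
],
[
"se",
"q"
],
[
"seq",
"uen"
],
[
"s",
"at"
],
[
"re",
"pr"
],
[
"repr",
"o"
],
[
"repro",
"c"
],
[
"reproc",
"es"
],
[
"reproces",
"sing</w>"
],
[
"p",
"reprocessing</w>"
],
[
"i",
"r"
],
[
"consis",
"ts</w>"
],
[
"an",
"</w>"
],
[
"9",
"</w>"
],
[
"8",
"</w>"
],
[
"6",
"</w>"
],
[
"5",
"</w>"
],
[
"4",
"</w>"
],
[
"3",
"."
],
[
"3.",
"0</w>"
],
[
"0",
"0</w>"
]
]
}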