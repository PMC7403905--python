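variant	canonical_code
hegu	LI4
hé gǔ	LI4
hapgok	LI4
hap gok	LI4
taichong	LR3
taì chōng	LR3
tai chong	LR3
taechung	LR3
tae chung	LR3
zusanli	ST36
zú sān lǐ	ST36
zu san li	ST36
joksamni	ST36
jok sam ni	ST36
sanyinjiao	SP6
sān yīn jiāo	SP6
san yin jiao	SP6
sameumgyo	SP6
sam eum gyo	SP6
neiguan	PC6
nèi guān	PC6
nei guan	PC6
naegwan	PC6
nae gwan	PC6
zhongwan	CV12
zhōng wǎn	CV12
zhong wan	CV12
jungwan	CV12
jung wan	CV12
baihui	GV20
bǎi huì	GV20
bai hui	GV20
baekhoe	GV20
baek hoe	GV20
taixi	KI3
taì xī	KI3
tai xi	KI3
taegye	KI3
tae gye	KI3
taibai	SP3
taì bái	SP3
tai bai	SP3
taebaek	SP3
tae baek	SP3
quchi	LI11
qū chí	LI11
qu chi	LI11
gokji	LI11
gok ji	LI11
danzhong	CV17
dàn zhōng	CV17
dan zhong	CV17
danjung	CV17
dan jung	CV17
shanzhong	CV17
yingu	KI10
yīn gǔ	KI10
eumgok	KI10
eum gok	KI10
ququan	LR8
qū quán	LR8
gokcheon	LR8
gok cheon	LR8
yinlingquan	SP9
yīn líng qúan	SP9
yin ling quan	SP9
eumneungcheon	SP9
eum neung cheon	SP9
fuliu	KI7
fù liū	KI7
buryu	KI7
bu ryu	KI7
shenmen	HT7
shén mén	HT7
yintang	EX-HN3
yìn táng	EX-HN3
fengchi	GB20
fēng chí	GB20
taiyuan	LU9
taì yuān	LU9
tinggong	SI19
tīng gōng	SI19
shenshu	BL23
shèn shū	BL23
weizhong	BL40
wèi zhōng	BL40
kunlun	BL60
kūn lún	BL60
huantiao	GB30
huán tiào	GB30
yanglingquan	GB34
yáng líng quán	GB34
jianjing	GB21
jiān jǐng	GB21
xuehai	SP10
xuè hǎi	SP10
dubi	ST35
dú bí	ST35
waixiyan	ST35
neixiyan	EX-LE4
nèi xī yǎn	EX-LE4
xiyan	EX-LE4
baxie	EX-UE9
bā xié	EX-UE9
guanyuan	CV4
guān yuán	CV4
qihai	CV6
liangmen	ST21
liáng mén	ST21
zhaohai	KI6
zhào hǎi	KI6
yinxi	HT6
yīn xì	HT6
yaoyangguan	GV3
yāo yáng guān	GV3
mingmen	GV4
dazhui	GV14
dà zhuī	GV14
zhongzhu	TE3
waiguan	TE5
waì guān	TE5
dachangshu	BL25
dà cháng shū	BL25
zhigou	TE6
taiyang	EX-HN5
zulinqi	GB41
xingjian	LR2
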